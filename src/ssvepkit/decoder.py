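"""Filter-bank task-discriminant component analysis (TDCA) decoding,
with an ensemble task-related component analysis (TRCA) baseline.

TDCA learns one set of spatiotemporal filters shared by all targets.  Each
trial (channels x samples) is delay-embedded with order ``l`` (stacking the
signal at lags 0..l), then augmented along the time axis with its projection
onto the sine-cosine reference subspace of the class frequency.  Class
templates are the mean augmented trials; the filters W maximize the Fisher
ratio of between-class to within-class scatter built from the augmented
data.  Classification correlates the filtered test trial against each
filtered template per subband and fuses the squared correlations with the
harmonic weights f_m = m^-1.25 + 0.25.

Test trials shorter than the training window are scored by zero-padding the
delay embedding, which is also how the trailing ``l`` lag samples are
handled at test time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
from scipy import linalg

from .containers import EpochSet

__all__ = [
    "delay_embed",
    "reference_projection",
    "subband_weights",
    "TDCAModel",
    "ScoreVector",
    "fit_tdca",
    "score",
    "score_batch",
    "TRCAModel",
    "fit_trca",
    "score_trca",
    "score_batch_trca",
]


def subband_weights(n_subbands: int) -> np.ndarray:
    """Harmonic-decay fusion weights f_m = m^-1.25 + 0.25."""
    m = np.arange(1, n_subbands + 1, dtype=float)
    return m ** -1.25 + 0.25


def _fkey(f: float) -> float:
    """Canonical dict key for a stimulus frequency (stable to 1 uHz)."""
    return round(float(f), 6)


# ----------------------------------------------------------- embeddings
def delay_embed(
    X: np.ndarray, l: int, test_mode: bool = False, n_out: int | None = None
) -> np.ndarray:
    """Stack the signal at lags 0..l into ((l+1)*Nc, n_out).

    Row block j at column t holds X[:, t + j].  In training mode the source
    must extend ``l`` samples past the output window, so every entry is real
    data; in test mode unavailable trailing samples are zero-padded.
    """
    if l < 0:
        raise ValueError("delay order l must be non-negative")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    nc, n_avail = X.shape
    if n_out is None:
        n_out = n_avail if test_mode else n_avail - l
    if n_out <= 0:
        raise ValueError("output window is empty")
    if not test_mode and n_avail < n_out + l:
        raise ValueError(
            f"training data must extend l={l} samples past the window "
            f"({n_out} + {l} > {n_avail} available)"
        )
    out = np.zeros(((l + 1) * nc, n_out))
    for j in range(l + 1):
        valid = min(n_out, max(n_avail - j, 0))
        out[j * nc : (j + 1) * nc, :valid] = X[:, j : j + valid]
    return out


def _embed_batch(data: np.ndarray, l: int, n_out: int) -> np.ndarray:
    """Vectorized zero-padded delay embedding of (N, Nc, n_avail) trials."""
    n_trials, nc, n_avail = data.shape
    out = np.zeros((n_trials, (l + 1) * nc, n_out))
    for j in range(l + 1):
        valid = min(n_out, max(n_avail - j, 0))
        out[:, j * nc : (j + 1) * nc, :valid] = data[:, :, j : j + valid]
    return out


def reference_projection(f: float, n_harmonics: int, fs: float, n_samples: int) -> np.ndarray:
    """Orthogonal projector onto the sine-cosine reference subspace.

    Y stacks sin(2*pi*h*f*t) and cos(2*pi*h*f*t) for h = 1..Nh; the
    returned P = Y^T (Y Y^T)^-1 Y is symmetric and idempotent and is applied
    on the right, X_p = X @ P.
    """
    if n_harmonics * f >= fs / 2:
        raise ValueError(
            f"{n_harmonics} harmonics of {f} Hz exceed the Nyquist limit {fs / 2} Hz"
        )
    t = np.arange(n_samples) / fs
    y = np.empty((2 * n_harmonics, n_samples))
    for h in range(1, n_harmonics + 1):
        y[2 * (h - 1)] = np.sin(2 * np.pi * h * f * t)
        y[2 * h - 1] = np.cos(2 * np.pi * h * f * t)
    gram = y @ y.T
    if n_samples < 2 * n_harmonics or np.linalg.matrix_rank(gram) < 2 * n_harmonics:
        warnings.warn(
            "sine-cosine reference matrix is rank deficient; using a pseudo-inverse",
            stacklevel=2,
        )
        return y.T @ np.linalg.pinv(gram) @ y
    return y.T @ np.linalg.solve(gram, y)


# ------------------------------------------------------------- TDCA fit
@dataclass
class TDCAModel:
    """Per-subband spatiotemporal filters plus filtered class templates."""

    filters: list[np.ndarray]  # per subband, ((l+1)*Nc, D)
    templates: list[np.ndarray]  # per subband, (Nt, D, 2*Np) filtered class means
    projections: dict[float, np.ndarray]  # per stimulus frequency, (Np, Np)
    class_list: np.ndarray  # sorted target ids
    class_freqs: np.ndarray  # Hz, aligned with class_list
    delay_order: int
    n_components: int
    n_harmonics_ref: int
    fs: float
    np_train: int
    n_channels: int

    @property
    def n_subbands(self) -> int:
        return len(self.filters)

    # -------------------------------------------------------------- I/O
    def to_hdf5(self, path) -> None:
        with h5py.File(Path(path), "w") as f:
            for m, (w, t) in enumerate(zip(self.filters, self.templates), start=1):
                f.create_dataset(f"filters/subband_{m}", data=w)
                f.create_dataset(f"templates/subband_{m}", data=t)
            for freq, p in self.projections.items():
                f.create_dataset(f"projections/f_{freq:.6f}", data=p)
            f.attrs.update(
                {
                    "delay_order": self.delay_order,
                    "n_components": self.n_components,
                    "n_harmonics_ref": self.n_harmonics_ref,
                    "fs": self.fs,
                    "np_train": self.np_train,
                    "n_channels": self.n_channels,
                }
            )
            f.create_dataset("class_list", data=self.class_list)
            f.create_dataset("class_freqs", data=self.class_freqs)

    @classmethod
    def from_hdf5(cls, path) -> "TDCAModel":
        with h5py.File(Path(path), "r") as f:
            n_sub = len(f["filters"])
            filters = [f[f"filters/subband_{m}"][()] for m in range(1, n_sub + 1)]
            templates = [f[f"templates/subband_{m}"][()] for m in range(1, n_sub + 1)]
            projections = {
                _fkey(k[2:]): f[f"projections/{k}"][()] for k in f["projections"]
            }
            return cls(
                filters=filters,
                templates=templates,
                projections=projections,
                class_list=f["class_list"][()],
                class_freqs=f["class_freqs"][()],
                delay_order=int(f.attrs["delay_order"]),
                n_components=int(f.attrs["n_components"]),
                n_harmonics_ref=int(f.attrs["n_harmonics_ref"]),
                fs=float(f.attrs["fs"]),
                np_train=int(f.attrs["np_train"]),
                n_channels=int(f.attrs["n_channels"]),
            )


@dataclass
class ScoreVector:
    """Fused per-class features, per-subband correlations and the decision."""

    rho: np.ndarray  # (Nt,)
    r: np.ndarray  # (Nt, Nm)
    predicted: int


def _augment_trials(
    data: np.ndarray,
    labels: np.ndarray,
    freq_of: dict[int, float],
    projections: dict[float, np.ndarray],
    l: int,
    np_train: int,
) -> np.ndarray:
    """Delay-embed and reference-augment training trials.

    Returns (rows, N, 2*Np) - row-major across trials, so the scatter
    matrices can be formed by a zero-copy reshape.
    """
    n_trials, nc, _ = data.shape
    rows = (l + 1) * nc
    src = np.ascontiguousarray(data[:, :, : np_train + l].transpose(1, 0, 2))
    out = np.zeros((rows, n_trials, 2 * np_train))
    for j in range(l + 1):
        out[j * nc : (j + 1) * nc, :, :np_train] = src[:, :, j : j + np_train]
    emb = out[:, :, :np_train]
    # trials arrive sorted by stimulus frequency, so each reference
    # projection applies to one contiguous slice
    ftrial = np.array([freq_of[int(t)] for t in labels])
    bounds = np.flatnonzero(np.r_[True, np.diff(ftrial) != 0, True])
    for s, e in zip(bounds[:-1], bounds[1:]):
        out[:, s:e, np_train:] = emb[:, s:e, :] @ projections[_fkey(ftrial[s])]
    return out


def difference_matrices(
    xa_rt: np.ndarray, labels: np.ndarray, class_list: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class means plus between- (Hb) and within-class (Hw) difference
    matrices from augmented trials in (rows, N, 2*Np) layout.

    Hb stacks the class means minus the grand mean (rows x Nt*2Np); Hw
    stacks every trial minus its class mean (rows x N*2Np).  ``xa_rt`` is
    consumed (centered in place).
    """
    rows = xa_rt.shape[0]
    means = np.stack(
        [xa_rt[:, labels == t, :].mean(axis=1) for t in class_list], axis=1
    )  # (rows, Nt, 2*Np)
    grand = means.mean(axis=1, keepdims=True)
    hb = np.ascontiguousarray(means - grand).reshape(rows, -1)
    for i, t in enumerate(class_list):
        idx = labels == t
        xa_rt[:, idx, :] -= means[:, i : i + 1, :]
    hw = xa_rt.reshape(rows, -1)
    return means.transpose(1, 0, 2), hb, hw


def _scatter_matrices(
    xa_rt: np.ndarray, labels: np.ndarray, class_list: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class means plus Hb*Hb' and Hw*Hw' scatter matrices.

    The rank-k accumulation runs in single precision (the scatters feed a
    heavily ridge-regularized eigenproblem on statistical estimates, where
    float32 accumulation error is orders of magnitude below the sampling
    noise) and is symmetrized afterwards.
    """
    from scipy.linalg.blas import ssyrk

    means, hb, hw = difference_matrices(xa_rt, labels, class_list)
    sb = ssyrk(1.0, hb.astype(np.float32), trans=0)
    sw = ssyrk(1.0, hw.astype(np.float32), trans=0)
    sb = np.triu(sb) + np.triu(sb, 1).T
    sw = np.triu(sw) + np.triu(sw, 1).T
    return means, sb.astype(float), sw.astype(float)


def fit_tdca(
    subbands: Sequence[EpochSet],
    frequencies: dict[int, float],
    n_samples: int,
    *,
    delay_order: int = 4,
    n_components: int = 8,
    n_harmonics_ref: int = 5,
    ridge: float = 1e-6,
) -> TDCAModel:
    """Fit filter-bank TDCA on per-subband filtered training epochs.

    ``frequencies`` maps target_id to stimulus frequency.  Training epochs
    must extend ``delay_order`` samples past ``n_samples``.
    """
    first = subbands[0]
    labels = first.labels
    class_list = np.unique(labels)
    counts = {int(t): int(np.sum(labels == t)) for t in class_list}
    if min(counts.values()) < 2:
        few = [t for t, c in counts.items() if c < 2]
        raise ValueError(f"need >= 2 training trials per class; too few for {few}")
    missing = [int(t) for t in class_list if int(t) not in frequencies]
    if missing:
        raise ValueError(f"no stimulus frequency for target ids {missing}")
    if first.n_samples < n_samples + delay_order:
        raise ValueError(
            f"training epochs must hold n_samples + l = {n_samples + delay_order} "
            f"samples, got {first.n_samples}"
        )
    fs = first.fs
    class_freqs = np.array([frequencies[int(t)] for t in class_list])
    projections = {
        _fkey(f): reference_projection(f, n_harmonics_ref, fs, n_samples)
        for f in np.unique(class_freqs)
    }
    # sort trials by (frequency, label) so reference projections and class
    # reductions act on contiguous slices
    ftrial = np.array([frequencies[int(t)] for t in labels])
    order = np.lexsort((labels, ftrial))
    labels = labels[order]
    filters, templates = [], []
    for es in subbands:
        xa = _augment_trials(
            es.data[order], labels, frequencies, projections, delay_order, n_samples
        )
        rows = xa.shape[0]
        means, sb, sw = _scatter_matrices(xa, labels, class_list)
        # absolute floor covers float32 rounding of the rank-k accumulation,
        # which can leave Sw marginally indefinite
        eps = (
            ridge * np.trace(sw) / rows
            + 1e-7 * np.trace(sw)
            + 1e-12 * (np.trace(sb) / rows + 1.0)
        )
        vals = vecs = None
        for _ in range(4):
            try:
                vals, vecs = linalg.eigh(sb, sw + eps * np.eye(rows))
                break
            except linalg.LinAlgError:
                eps *= 100.0
        if vecs is None:
            raise ValueError(
                "within-class scatter is singular despite ridge "
                f"(eps={eps:.3e}); increase the ridge or the trial count"
            )
        w = vecs[:, ::-1][:, :n_components]
        filters.append(w)
        templates.append(np.einsum("rd,nrt->ndt", w, means))
    return TDCAModel(
        filters=filters,
        templates=templates,
        projections=projections,
        class_list=class_list,
        class_freqs=class_freqs,
        delay_order=delay_order,
        n_components=n_components,
        n_harmonics_ref=n_harmonics_ref,
        fs=fs,
        np_train=n_samples,
        n_channels=first.n_channels,
    )


# ----------------------------------------------------------- TDCA score
def _normalize_rows(v: np.ndarray, what: str) -> np.ndarray:
    """Center and unit-normalize the last axis; zero-variance rows -> 0."""
    v = v - v.mean(axis=-1, keepdims=True)
    norms = np.linalg.norm(v, axis=-1, keepdims=True)
    bad = norms[..., 0] == 0
    if np.any(bad):
        warnings.warn(f"zero-variance {what}; correlations set to 0", stacklevel=3)
        norms[norms == 0] = 1.0
    return v / norms


def score_batch(
    subband_trials: Sequence[np.ndarray], model: TDCAModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Score many trials at once.

    ``subband_trials[m]`` is (N, Nc, Np') with Np' <= the training window
    (shorter windows are zero-padded through the embedding).  Returns
    (rho (N, Nt), r (N, Nt, Nm), predicted labels (N,)).
    """
    np_train = model.np_train
    weights = subband_weights(model.n_subbands)
    n_trials = subband_trials[0].shape[0]
    n_classes = len(model.class_list)
    r_all = np.zeros((n_trials, n_classes, model.n_subbands))
    for m, (x, w, tmpl) in enumerate(
        zip(subband_trials, model.filters, model.templates)
    ):
        x = np.asarray(x, dtype=float)
        if x.ndim != 3 or x.shape[1] != model.n_channels:
            raise ValueError(
                f"subband {m + 1}: expected (N, {model.n_channels}, Np'), got {x.shape}"
            )
        if x.shape[2] > np_train:
            raise ValueError(
                f"test window {x.shape[2]} exceeds the training window {np_train}"
            )
        emb = _embed_batch(x, model.delay_order, np_train)
        z = np.einsum("rd,nrt->ndt", w, emb)
        v = _normalize_rows(tmpl.reshape(n_classes, -1), "template projection")
        for f in np.unique(model.class_freqs):
            cols = np.flatnonzero(model.class_freqs == f)
            zp = z @ model.projections[_fkey(f)]
            u = np.concatenate([z, zp], axis=2).reshape(n_trials, -1)
            u = _normalize_rows(u, "trial projection")
            r_all[:, cols, m] = u @ v[cols].T
    rho = np.einsum("ncm,m->nc", r_all ** 2, weights)
    predicted = model.class_list[np.argmax(rho, axis=1)]
    return rho, r_all, predicted


def score(subband_trial: Sequence[np.ndarray], model: TDCAModel) -> ScoreVector:
    """Score a single trial given as one (Nc, Np') array per subband."""
    batches = [np.asarray(x)[None, :, :] for x in subband_trial]
    rho, r, pred = score_batch(batches, model)
    return ScoreVector(rho=rho[0], r=r[0], predicted=int(pred[0]))


# ------------------------------------------------------------------ TRCA
@dataclass
class TRCAModel:
    """Ensemble TRCA baseline: per-class filters stacked across classes."""

    filters: list[np.ndarray]  # per subband, (Nc, Nt) ensemble
    templates: list[np.ndarray]  # per subband, (Nt, Nt_comp, Np) filtered means
    class_list: np.ndarray
    fs: float
    np_train: int
    n_channels: int

    @property
    def n_subbands(self) -> int:
        return len(self.filters)


def fit_trca(
    subbands: Sequence[EpochSet],
    n_samples: int,
    *,
    ridge: float = 1e-6,
) -> TRCAModel:
    """Fit ensemble TRCA: per class, the spatial filter maximizing
    inter-trial covariance; filters are concatenated across classes."""
    first = subbands[0]
    labels = first.labels
    class_list = np.unique(labels)
    for t in class_list:
        if np.sum(labels == t) < 2:
            raise ValueError(
                f"class {int(t)}: inter-trial covariance needs >= 2 trials per class"
            )
    filters, templates = [], []
    for es in subbands:
        data = es.data[:, :, :n_samples]
        ws = []
        means = []
        for t in class_list:
            xc = data[labels == t]
            xc = xc - xc.mean(axis=2, keepdims=True)
            total = xc.sum(axis=0)
            q = np.einsum("ict,idt->cd", xc, xc)
            s = total @ total.T - q
            eps = ridge * np.trace(q) / q.shape[0] + 1e-12 * (np.trace(np.abs(s)) + 1.0)
            vals, vecs = linalg.eigh(s, q + eps * np.eye(q.shape[0]))
            ws.append(vecs[:, -1])
            means.append(xc.mean(axis=0))
        w = np.stack(ws, axis=1)  # (Nc, Nt)
        filters.append(w)
        templates.append(np.stack([w.T @ m for m in means]))
    return TRCAModel(
        filters=filters,
        templates=templates,
        class_list=class_list,
        fs=first.fs,
        np_train=n_samples,
        n_channels=first.n_channels,
    )


def score_batch_trca(
    subband_trials: Sequence[np.ndarray], model: TRCAModel
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble-TRCA scores: (rho (N, Nt), predicted labels (N,))."""
    weights = subband_weights(model.n_subbands)
    n_trials = subband_trials[0].shape[0]
    n_classes = len(model.class_list)
    r_all = np.zeros((n_trials, n_classes, model.n_subbands))
    for m, (x, w, tmpl) in enumerate(
        zip(subband_trials, model.filters, model.templates)
    ):
        x = np.asarray(x, dtype=float)
        if x.shape[2] != model.np_train:
            raise ValueError(
                f"TRCA requires the training window {model.np_train}, got {x.shape[2]}"
            )
        xc = x - x.mean(axis=2, keepdims=True)
        z = np.einsum("cd,nct->ndt", w, xc).reshape(n_trials, -1)
        z = _normalize_rows(z, "trial projection")
        v = _normalize_rows(tmpl.reshape(n_classes, -1), "template projection")
        r_all[:, :, m] = z @ v.T
    rho = np.einsum("ncm,m->nc", r_all ** 2, weights)
    return rho, model.class_list[np.argmax(rho, axis=1)]


def score_trca(subband_trial: Sequence[np.ndarray], model: TRCAModel) -> ScoreVector:
    batches = [np.asarray(x)[None, :, :] for x in subband_trial]
    rho, pred = score_batch_trca(batches, model)
    return ScoreVector(rho=rho[0], r=np.zeros((len(rho[0]), model.n_subbands)), predicted=int(pred[0]))
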