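"""Greedy backward electrode elimination.

Starting from a full configuration, each step evaluates every subset
obtained by removing exactly one electrode, keeps the subset with the best
mean accuracy over the supplied datasets, and repeats until two electrodes
remain.  The best subset and accuracy at every size are recorded.  Ties are
broken by removing the lexicographically-last channel name, which makes the
search deterministic for a deterministic evaluator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import pandas as pd

__all__ = ["GreedyPath", "greedy_backward"]

Evaluator = Callable[[tuple[str, ...]], float]


@dataclass
class GreedyPath:
    """Best subset and mean accuracy for every electrode count."""

    sizes: list[int]
    subsets: list[tuple[str, ...]]
    accuracies: list[float]
    task_label: str = ""
    initial_config: str = ""
    step_log: pd.DataFrame | None = None  # every candidate evaluated

    def to_json(self, path) -> None:
        payload = [
            {"size": s, "channels": list(c), "mean_accuracy": a}
            for s, c, a in zip(self.sizes, self.subsets, self.accuracies)
        ]
        with open(path, "w") as f:
            json.dump(
                {
                    "task_label": self.task_label,
                    "initial_config": self.initial_config,
                    "path": payload,
                },
                f,
                indent=2,
            )

    def best(self) -> tuple[int, tuple[str, ...], float]:
        i = max(range(len(self.sizes)), key=lambda j: (self.accuracies[j], -self.sizes[j]))
        return self.sizes[i], self.subsets[i], self.accuracies[i]


def greedy_backward(
    channels: Sequence[str],
    evaluator: Evaluator,
    *,
    min_size: int = 2,
    task_label: str = "",
    initial_config: str = "",
    cache: dict | None = None,
) -> GreedyPath:
    """Run the backward elimination from the full channel set.

    ``evaluator`` maps an ordered channel tuple to a mean accuracy and must
    be deterministic; results are cached on the sorted subset so repeated
    candidates cost nothing.  Raises with the failing subset named if the
    evaluator errors.
    """
    current = tuple(channels)
    if len(current) < 3:
        raise ValueError("need at least 3 initial channels")
    if len(set(current)) != len(current):
        raise ValueError("duplicate channel names")
    cache = {} if cache is None else cache

    def ev(subset: tuple[str, ...]) -> float:
        key = tuple(sorted(subset))
        if key not in cache:
            try:
                cache[key] = float(evaluator(subset))
            except Exception as e:
                raise RuntimeError(f"evaluator failed on subset {subset}: {e}") from e
        return cache[key]

    sizes, subsets, accuracies, log = [], [], [], []
    acc = ev(current)
    sizes.append(len(current))
    subsets.append(current)
    accuracies.append(acc)
    while len(current) > min_size:
        best_sub, best_acc, best_removed = None, -float("inf"), None
        for ch in current:
            cand = tuple(c for c in current if c != ch)
            a = ev(cand)
            log.append(
                {"size": len(cand), "removed": ch, "mean_accuracy": a}
            )
            # ties: prefer removing the lexicographically-last channel
            if a > best_acc or (a == best_acc and ch > (best_removed or "")):
                best_sub, best_acc, best_removed = cand, a, ch
        current = best_sub
        sizes.append(len(current))
        subsets.append(current)
        accuracies.append(best_acc)
    return GreedyPath(
        sizes=sizes,
        subsets=subsets,
        accuracies=accuracies,
        task_label=task_label,
        initial_config=initial_config,
        step_log=pd.DataFrame(log),
    )
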