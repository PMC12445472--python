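"""Comparative benchmarking: method x entropy grids, ranking, Wilcoxon tests.

Four method combinations are compared — PSO and DE, each driving either the
classical (CR) or the quantum (QR) Renyi objective.  For every
(image, k, method) cell the pipeline runs once, the nine quality metrics
are computed, and methods are ranked per metric by mean value (direction:
AMBE lower-is-better, all others higher), with ties broken by lower
variance and then by method name.  The overall rank (OR) of a method is the
sum of its nine per-metric ranks; lower is better.  Paired per-image metric
values feed two-sided Wilcoxon signed-rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .entropy import EntropyParams
from .fixtures import FixtureSpec, make_piecewise_image
from .histogram import GrayImage, load_gray_image
from .metrics import HIGHER_IS_BETTER, METRIC_NAMES, compute_metrics
from .optimize import OptimizerConfig
from .segment import enhance_contrast, segment_image

__all__ = [
    "METHODS",
    "ComparisonTable",
    "rank_methods",
    "wilcoxon_signed_rank",
    "run_benchmark",
]

#: method name -> (optimizer, entropy mode)
METHODS: dict[str, tuple[str, str]] = {
    "PSO-CR": ("pso", "classical"),
    "DE-CR": ("de", "classical"),
    "PSO-QR": ("pso", "quantum"),
    "DE-QR": ("de", "quantum"),
}


@dataclass(frozen=True)
class ComparisonTable:
    """Per-run rows, per-(k, metric) ranks, overall ranks, Wilcoxon tests."""

    rows: pd.DataFrame
    ranks: pd.DataFrame        # index (k, metric), columns methods
    overall: pd.DataFrame      # index k, columns methods; OR = sum of ranks
    wilcoxon: pd.DataFrame     # columns: k, metric, pair, W, p (may be empty)
    failures: tuple[str, ...] = ()


def rank_methods(values: Mapping[str, Sequence[float]],
                 higher_is_better: bool = True) -> dict[str, int]:
    """Rank methods 1..n by mean; ties by lower variance, then name order."""
    if not values or any(len(v) == 0 for v in values.values()):
        raise ValueError("every method needs a non-empty list of values")
    stats_by_method = {
        name: (float(np.mean(v)), float(np.var(v))) for name, v in values.items()
    }
    ordered = sorted(
        stats_by_method,
        key=lambda m: (
            -stats_by_method[m][0] if higher_is_better else stats_by_method[m][0],
            stats_by_method[m][1],
            m,
        ),
    )
    return {name: rank for rank, name in enumerate(ordered, start=1)}


def _exact_two_sided_p(doubled_ranks: np.ndarray, doubled_w: int) -> float:
    """Exact sign-flip null of the rank sum, via the generating polynomial.

    ``doubled_ranks`` are 2x the (possibly tied, average) ranks so they are
    integers; counts fit exactly in float64 for n <= 25.
    """
    S = int(doubled_ranks.sum())
    dist = np.zeros(S + 1)
    dist[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: S + 1 - r]
        dist = dist + shifted
    total = 2.0 ** len(doubled_ranks)
    p = (dist[: doubled_w + 1].sum() + dist[S - doubled_w:].sum()) / total
    return float(min(p, 1.0))


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test with W = min(R+, R-).

    Zero differences are dropped; tied absolute differences receive average
    ranks.  The p-value uses the exact sign-flip null for n <= 25 and a
    tie-corrected normal approximation (with continuity correction) above.
    Fewer than 5 nonzero differences is a refusal.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n < 5:
        raise ValueError(f"need at least 5 nonzero differences, got {n}")
    ranks = stats.rankdata(np.abs(d))
    r_pos = float(ranks[d > 0].sum())
    r_neg = float(ranks[d < 0].sum())
    W = min(r_pos, r_neg)
    if n <= 25:
        doubled = np.rint(2 * ranks).astype(np.int64)
        p = _exact_two_sided_p(doubled, int(round(2 * W)))
    else:
        mu = n * (n + 1) / 4.0
        sigma = np.sqrt(float((ranks**2).sum()) / 4.0)  # tie-corrected
        z = (W - mu + 0.5) / sigma
        p = float(min(1.0, 2.0 * stats.norm.cdf(z)))
    return W, p


def _resolve_image(item, index: int) -> tuple[str, GrayImage]:
    if isinstance(item, GrayImage):
        return f"image{index}", item
    if isinstance(item, FixtureSpec):
        img, _ = make_piecewise_image(item)
        return f"fixture{index}(seed={item.seed})", img
    path = Path(item)
    return path.name, load_gray_image(path)


def run_benchmark(images: Sequence, ks: Sequence[int],
                  methods: Sequence[str] = tuple(METHODS),
                  config: OptimizerConfig | None = None,
                  alpha: float = 0.01,
                  seed: int = 0,
                  enhance: str = "identity",
                  compare_to: str = "enhanced",
                  min_pairs: int = 5) -> ComparisonTable:
    """Run the full method x entropy grid over an image set.

    ``images`` may mix file paths, :class:`GrayImage` objects and
    :class:`FixtureSpec` generators.  ``compare_to`` selects the metric
    reference: the image actually segmented (``"enhanced"``) or the raw
    original (``"raw"``).  Per-run seeds are derived deterministically from
    ``seed``.  Per-image failures are recorded and skipped.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if compare_to not in ("enhanced", "raw"):
        raise ValueError(f"compare_to must be 'enhanced' or 'raw', got {compare_to!r}")
    config = config or OptimizerConfig()
    resolved = [_resolve_image(item, i) for i, item in enumerate(images)]

    rows: list[dict] = []
    failures: list[str] = []
    ss = np.random.SeedSequence(seed)
    run_seeds = iter(ss.generate_state(len(resolved) * len(ks) * len(methods)))
    for image_id, img in resolved:
        reference = img if compare_to == "raw" else enhance_contrast(img, enhance)
        for k in ks:
            for method in methods:
                run_seed = int(next(run_seeds) % (2**31))
                optimizer, mode = METHODS[method]
                try:
                    seg, opt = segment_image(
                        img, k,
                        params=EntropyParams(alpha=alpha, mode=mode),
                        config=replace(config, seed=run_seed),
                        method=optimizer,
                        enhance=enhance,
                    )
                    report = compute_metrics(reference, seg.as_gray_image())
                except Exception as exc:  # record and continue
                    failures.append(f"{image_id}/k={k}/{method}: {exc}")
                    continue
                rows.append({
                    "image": image_id, "method": method, "k": k,
                    **report.to_dict(),
                    "fitness": opt.best_fitness,
                    "iterations": opt.iterations_used,
                    "thresholds": opt.best_X.rows,
                    "seed": run_seed,
                })
    frame = pd.DataFrame(rows)

    rank_records: list[dict] = []
    wilcoxon_records: list[dict] = []
    for k in ks:
        sub = frame[frame["k"] == k] if len(frame) else frame
        if len(sub) == 0:
            continue
        per_method = {
            m: sub[sub["method"] == m] for m in methods
            if (sub["method"] == m).any()
        }
        for metric in METRIC_NAMES:
            values = {m: g[metric].tolist() for m, g in per_method.items()}
            ranks = rank_methods(values, HIGHER_IS_BETTER[metric])
            rank_records.append({"k": k, "metric": metric, **ranks})
            names = sorted(per_method)
            for i, m1 in enumerate(names):
                for m2 in names[i + 1:]:
                    v1, v2 = np.asarray(values[m1]), np.asarray(values[m2])
                    if v1.size != v2.size or (v1 != v2).sum() < min_pairs:
                        continue
                    W, p = wilcoxon_signed_rank(v1, v2)
                    wilcoxon_records.append(
                        {"k": k, "metric": metric, "pair": f"{m1}/{m2}",
                         "W": W, "p": p}
                    )
    ranks_frame = (pd.DataFrame(rank_records).set_index(["k", "metric"])
                   if rank_records else pd.DataFrame())
    overall = (ranks_frame.groupby(level="k").sum()
               if len(ranks_frame) else pd.DataFrame())
    wilcoxon_frame = pd.DataFrame(
        wilcoxon_records, columns=["k", "metric", "pair", "W", "p"]
    )
    return ComparisonTable(rows=frame, ranks=ranks_frame, overall=overall,
                           wilcoxon=wilcoxon_frame, failures=tuple(failures))
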