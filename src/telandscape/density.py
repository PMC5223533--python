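"""Windowed TE-density tracks and k-means chromosome landscapes.

A TE is counted in a window iff its *start* position falls inside the
window, so with non-overlapping windows (the default, step = size) the
window counts sum exactly to the number of TE copies.  Clusters from
k-means on the genic-TE counts are relabeled by ascending cluster mean —
low / medium / high for the default k = 3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import ChromosomeSpec, TECopy, ValidationError, check_unique_chroms
from .assignment import AssignmentRecord

DEFAULT_WINDOW_BP = 100_000


@dataclass(frozen=True)
class WindowVector:
    chrom: str
    window_start: int
    window_size: int
    all_te_count: int
    genic_te_count: int

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValidationError("window_size must be > 0")
        if self.genic_te_count > self.all_te_count:
            raise ValidationError("genic_te_count cannot exceed all_te_count")


def window_te_density(
    tes: Sequence[TECopy],
    assignments: Sequence[AssignmentRecord],
    chroms: Sequence[ChromosomeSpec],
    window_bp: int = DEFAULT_WINDOW_BP,
    step_bp: int | None = None,
) -> list[WindowVector]:
    """Count all TEs and genic TEs per window along each chromosome.

    Windows start at 0 and advance by ``step_bp`` (default: ``window_bp``,
    i.e. non-overlapping); the final partial window is retained.  The genic
    flag is the assignment's any-overlap gene-region rule.
    """
    if step_bp is None:
        step_bp = window_bp
    if not (window_bp >= step_bp >= 1):
        raise ValidationError("require window_bp >= step_bp >= 1")
    lengths = check_unique_chroms(chroms)
    starts_by_chrom: dict[str, list[tuple[int, bool]]] = {c: [] for c in lengths}
    for te, rec in zip(tes, assignments):
        starts_by_chrom[te.span.chrom].append((te.span.start, rec.genic))

    out: list[WindowVector] = []
    for chrom in sorted(lengths):
        length = lengths[chrom]
        pts = starts_by_chrom[chrom]
        starts = np.array([p[0] for p in pts], dtype=np.int64)
        genic = np.array([p[1] for p in pts], dtype=bool)
        w = 0
        while True:
            hi = min(w + window_bp, length)
            in_win = (starts >= w) & (starts < hi)
            out.append(
                WindowVector(
                    chrom=chrom,
                    window_start=w,
                    window_size=hi - w,
                    all_te_count=int(in_win.sum()),
                    genic_te_count=int((in_win & genic).sum()),
                )
            )
            if hi >= length:
                break
            w += step_bp
    return out


def windows_to_frame(windows: Sequence[WindowVector]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "window_start": [w.window_start for w in windows],
            "window_size": [w.window_size for w in windows],
            "all_te_count": [w.all_te_count for w in windows],
            "genic_te_count": [w.genic_te_count for w in windows],
        }
    )


_K3_NAMES = {1: ("low",), 2: ("low", "high"), 3: ("low", "medium", "high")}


def kmeans_density_clusters(
    windows: Sequence[WindowVector],
    k: int = 3,
    seed: int = 0,
) -> list[str]:
    """Cluster windows by genic-TE count; labels ordered by cluster mean.

    Seeded k-means++ with 10 restarts; deterministic for a fixed seed.
    For k <= 3 the labels are low(/medium)/high; larger k falls back to
    ``level_0`` .. ``level_{k-1}`` in ascending-mean order.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(windows):
        raise ValidationError(f"k={k} exceeds number of windows {len(windows)}")
    x = np.array([[w.genic_te_count] for w in windows], dtype=float)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(x)
    order = np.argsort(km.cluster_centers_.ravel(), kind="stable")
    names = _K3_NAMES.get(k, tuple(f"level_{i}" for i in range(k)))
    rank_of = {int(cluster): names[rank] for rank, cluster in enumerate(order)}
    return [rank_of[int(c)] for c in raw]
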