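"""Temporal QTL calling from the time point x SNP significance landscape.

A SNP is called when its association recurs: -log10 p >= threshold at a
minimum number of time points within the LL phase or within the HL phase.
Each called SNP spawns a fixed window (default 100 kb either side);
overlapping or touching windows on a chromosome merge into one QTL
interval, numbered genome-wide by position.  Each interval is then
classified by *when* its top SNP is significant: LL-specific, early HL,
late HL, persistent HL, or LL+HL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gwas import ScanResult
from .schedule import MeasurementSchedule

__all__ = [
    "SignificanceGrid",
    "QtlInterval",
    "grid_from_scans",
    "call_qtl_snps",
    "window_merge",
    "classify_temporal",
    "call_and_classify",
]

TEMPORAL_CLASS_NAMES = ("LL", "earlyHL", "lateHL", "persistentHL", "LL+HL")


@dataclass
class SignificanceGrid:
    """SNPs x time points matrix of -log10 p with the genomic map."""

    neglog10p: np.ndarray  # (n_snps, n_timepoints)
    chrom: np.ndarray
    pos: np.ndarray
    schedule: MeasurementSchedule

    def __post_init__(self) -> None:
        self.neglog10p = np.asarray(self.neglog10p, dtype=float)
        if self.neglog10p.shape != (len(self.pos), len(self.schedule)):
            raise ValueError("grid shape does not match map/schedule")
        if (self.neglog10p < 0).any():
            raise ValueError("-log10 p entries must be non-negative")

    @property
    def n_snps(self) -> int:
        return self.neglog10p.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.neglog10p,
            columns=self.schedule.labels(),
        )
        df.insert(0, "pos", self.pos)
        df.insert(0, "chrom", self.chrom)
        return df


def grid_from_scans(
    scans: list[ScanResult], schedule: MeasurementSchedule
) -> SignificanceGrid:
    """Stack per-time-point scan results into a significance grid."""
    if len(scans) != len(schedule):
        raise ValueError("one scan per scheduled time point required")
    first = scans[0].table
    mat = np.column_stack([s.table["neglog10p"].to_numpy() for s in scans])
    return SignificanceGrid(
        neglog10p=mat,
        chrom=first["chrom"].to_numpy(),
        pos=first["pos"].to_numpy(),
        schedule=schedule,
    )


@dataclass
class QtlInterval:
    """A merged QTL window with its top SNP and temporal class."""

    qtl_id: int
    chrom: str
    start: int
    end: int
    top_pos: int
    top_neglog10p: float
    supporting_timepoints: list[str] = field(default_factory=list)
    temporal_class: str | None = None


def call_qtl_snps(
    grid: SignificanceGrid,
    threshold: float = 4.0,
    min_recurrence: int = 3,
) -> pd.DataFrame:
    """Per-SNP recurrence counts and the called flag.

    A SNP qualifies when it reaches ``-log10 p >= threshold`` at
    ``min_recurrence`` or more LL time points, or at that many HL time
    points (phase counts are not pooled).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_recurrence < 1:
        raise ValueError("min_recurrence must be >= 1")
    hits = grid.neglog10p >= threshold
    ll = grid.schedule.ll_indices
    hl = grid.schedule.hl_indices
    n_ll = hits[:, ll].sum(axis=1)
    n_hl = hits[:, hl].sum(axis=1)
    return pd.DataFrame(
        {
            "chrom": grid.chrom,
            "pos": grid.pos,
            "ll_hits": n_ll,
            "hl_hits": n_hl,
            "called": (n_ll >= min_recurrence) | (n_hl >= min_recurrence),
        }
    )


def window_merge(
    grid: SignificanceGrid,
    called: pd.DataFrame | np.ndarray,
    half_window: int = 100_000,
    chromosome_lengths: dict[str, int] | None = None,
) -> list[QtlInterval]:
    """Merge fixed windows around called SNPs into QTL intervals.

    Each called SNP contributes [pos - half_window, pos + half_window]
    clipped to [1, chromosome length]; overlapping *or touching* windows
    on one chromosome are lumped into one interval.  The interval's top
    SNP is its maximal -log10 p over all time points (ties broken by the
    smaller position) and intervals are numbered genome-wide by
    chromosome then start position.
    """
    mask = called["called"].to_numpy() if isinstance(called, pd.DataFrame) else np.asarray(called, bool)
    best = grid.neglog10p.max(axis=1)
    intervals: list[QtlInterval] = []
    chrom_order = []
    for c in grid.chrom:
        if c not in chrom_order:
            chrom_order.append(c)
    for c in chrom_order:
        sel = np.where((grid.chrom == c) & mask)[0]
        if sel.size == 0:
            continue
        clen = None if chromosome_lengths is None else chromosome_lengths.get(c)
        order = sel[np.argsort(grid.pos[sel], kind="stable")]
        cur_start = cur_end = None
        members: list[int] = []

        def flush():
            top = max(members, key=lambda j: (best[j], -grid.pos[j]))
            intervals.append(
                QtlInterval(
                    qtl_id=0,
                    chrom=c,
                    start=int(cur_start),
                    end=int(cur_end),
                    top_pos=int(grid.pos[top]),
                    top_neglog10p=float(best[top]),
                )
            )

        for j in order:
            s = max(int(grid.pos[j]) - half_window, 1)
            e = int(grid.pos[j]) + half_window
            if clen is not None:
                e = min(e, clen)
            if cur_start is None:
                cur_start, cur_end, members = s, e, [j]
            elif s <= cur_end:  # overlapping or touching
                cur_end = max(cur_end, e)
                members.append(j)
            else:
                flush()
                cur_start, cur_end, members = s, e, [j]
        if members:
            flush()
    for i, q in enumerate(intervals, start=1):
        q.qtl_id = i
    return intervals


def classify_temporal(
    q: QtlInterval,
    grid: SignificanceGrid,
    threshold: float = 4.0,
    min_recurrence: int = 3,
    hl_day_split: int = 2,
) -> str:
    """Temporal class of a QTL from its top SNP's significant time points.

    With S the set of significant time points: ``LL`` when only the LL
    count reaches the recurrence rule; ``LL+HL`` when both phases do;
    among HL-only QTLs, ``earlyHL`` when every HL hit falls in the first
    ``hl_day_split`` HL days, ``lateHL`` when every hit falls after them,
    and ``persistentHL`` when hits span both halves.
    """
    j = int(np.where((grid.chrom == q.chrom) & (grid.pos == q.top_pos))[0][0])
    sig = grid.neglog10p[j] >= threshold
    sched = grid.schedule
    labels = sched.labels()
    ll_hits = [i for i in sched.ll_indices if sig[i]]
    hl_hits = [i for i in sched.hl_indices if sig[i]]
    q.supporting_timepoints = [labels[i] for i in range(len(sched)) if sig[i]]
    ll_ok = len(ll_hits) >= min_recurrence
    hl_ok = len(hl_hits) >= min_recurrence
    if not (ll_ok or hl_ok):
        raise ValueError(
            f"QTL {q.qtl_id}: top SNP does not satisfy the recurrence rule"
        )
    if ll_ok and hl_ok:
        cls = "LL+HL"
    elif ll_ok:
        cls = "LL"
    else:
        days = [sched.hl_day_index(sched.time_points[i]) for i in hl_hits]
        early = all(d <= hl_day_split for d in days)
        late = all(d > hl_day_split for d in days)
        cls = "earlyHL" if early else ("lateHL" if late else "persistentHL")
    q.temporal_class = cls
    return cls


def call_and_classify(
    grid: SignificanceGrid,
    threshold: float = 4.0,
    min_recurrence: int = 3,
    half_window: int = 100_000,
    hl_day_split: int = 2,
    chromosome_lengths: dict[str, int] | None = None,
) -> list[QtlInterval]:
    """Full QTL pipeline: call SNPs, merge windows, classify intervals."""
    called = call_qtl_snps(grid, threshold, min_recurrence)
    qtls = window_merge(grid, called, half_window, chromosome_lengths)
    for q in qtls:
        classify_temporal(q, grid, threshold, min_recurrence, hl_day_split)
    return qtls


def qtl_table(qtls: list[QtlInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "qtl_id": q.qtl_id,
                "chrom": q.chrom,
                "start": q.start,
                "end": q.end,
                "top_snp_pos": q.top_pos,
                "top_neglog10p": q.top_neglog10p,
                "class": q.temporal_class,
                "supporting_timepoints": ",".join(q.supporting_timepoints),
            }
            for q in qtls
        ]
    )
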