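"""Sample-level aggregation of classified reads.

Produces the assay's quantitative outputs: per-class read counts, the
mutagenic-repair fraction, repair efficiency normalized to an induced
wildtype control, the microhomology spectrum of deletions, tornado tables
of mutagenic events sorted by size, and the dual-reporter repair score
(the %NHEJ-positive / %SSA-positive ratio of a test population divided by
the same ratio in the wildtype control).

PolyA-filtered and unalignable reads are excluded from both numerator and
denominator of the mutagenic fraction.  Wilson 95% intervals accompany
fractions; the repair score carries a delta-method standard error (it is
a ratio of ratios of binomial proportions).
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .classify import ClassifiedRead, MUTAGENIC_CLASSES, RepairClass

#: microhomology histogram bins as (label, lo, hi) with hi inclusive
DEFAULT_MH_BINS: tuple[tuple[str, int, float], ...] = (
    ("0", 0, 0),
    ("1", 1, 1),
    ("2", 2, 2),
    ("3-5", 3, 5),
    ("6-10", 6, 10),
    (">10", 11, math.inf),
)


class NormalizationError(ValueError):
    """Raised when a control sample cannot anchor a normalization."""


def wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score 95% CI for a binomial proportion."""
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


@dataclass(frozen=True)
class TornadoRecord:
    """One mutagenic event for the size-sorted tornado table."""

    repair_class: RepairClass
    del_start: Optional[int]
    del_end: Optional[int]
    ins_len: int
    event_size: int
    rank: int


@dataclass
class RepairSummary:
    sample_id: str
    class_counts: dict[RepairClass, int]
    n_aligned: int
    mutagenic_fraction: float
    mutagenic_fraction_ci: tuple[float, float]
    mutagenic_fraction_all_reads: float
    normalized_efficiency: Optional[float] = None
    mh_histogram: dict[str, float] = field(default_factory=dict)
    tornado: list[TornadoRecord] = field(default_factory=list)

    def to_json(self) -> str:
        d = {
            "sample_id": self.sample_id,
            "class_counts": {k.value: v for k, v in sorted(self.class_counts.items())},
            "n_aligned": self.n_aligned,
            "mutagenic_fraction": self.mutagenic_fraction,
            "mutagenic_fraction_ci": list(self.mutagenic_fraction_ci),
            "mutagenic_fraction_all_reads": self.mutagenic_fraction_all_reads,
            "normalized_efficiency": self.normalized_efficiency,
            "mh_histogram": self.mh_histogram,
            "n_mutagenic_events": len(self.tornado),
        }
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass(frozen=True)
class ReporterCounts:
    """Scored animals from the dual NHEJ/SSA reporter."""

    nhej_positive: int
    nhej_total: int
    ssa_positive: int
    ssa_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.nhej_positive <= self.nhej_total and self.nhej_total > 0):
            raise ValueError("invalid NHEJ counts")
        if not (0 <= self.ssa_positive <= self.ssa_total and self.ssa_total > 0):
            raise ValueError("invalid SSA counts")

    @property
    def ratio(self) -> float:
        """%NHEJ-positive divided by %SSA-positive."""
        if self.ssa_positive == 0:
            raise NormalizationError(
                "no SSA-positive animals: the repair score is undefined; "
                "report the unnormalized reporter percentages instead"
            )
        return (self.nhej_positive / self.nhej_total) / (self.ssa_positive / self.ssa_total)


def summarize_sample(
    classified: Sequence[ClassifiedRead],
    sample_id: str = "sample",
    mh_bins=DEFAULT_MH_BINS,
) -> RepairSummary:
    """Aggregate per-read classifications into a sample summary."""
    if not classified:
        raise ValueError("cannot summarize zero aligned reads")
    counts = Counter(r.repair_class for r in classified)
    n_aligned = len(classified)
    n_excluded = counts[RepairClass.FILTERED_POLYA] + counts[RepairClass.UNALIGNABLE]
    n_mut = sum(counts[c] for c in MUTAGENIC_CLASSES)
    denom = n_aligned - n_excluded
    frac = n_mut / denom if denom else 0.0
    ci = wilson_interval(n_mut, denom) if denom else (0.0, 0.0)
    return RepairSummary(
        sample_id=sample_id,
        class_counts=dict(counts),
        n_aligned=n_aligned,
        mutagenic_fraction=frac,
        mutagenic_fraction_ci=ci,
        mutagenic_fraction_all_reads=n_mut / n_aligned,
        mh_histogram=deletion_type_distribution(classified, mh_bins),
        tornado=make_tornado(classified),
    )


def normalize_to_control(sample: RepairSummary, control: RepairSummary) -> float:
    """Repair efficiency of a sample relative to an induced control.

    The sample's mutagenic fraction divided by the control's (the control
    being the break-induced wildtype population).
    """
    if control.mutagenic_fraction <= 0:
        raise NormalizationError("control sample has no mutagenic repair events")
    return sample.mutagenic_fraction / control.mutagenic_fraction


def deletion_type_distribution(
    classified: Sequence[ClassifiedRead], bins=DEFAULT_MH_BINS
) -> dict[str, float]:
    """Microhomology spectrum over deletion-bearing mutagenic reads.

    Fraction of deletion-carrying mutagenic reads falling into each
    junction-microhomology bin; empty when the sample has no deletions.
    """
    _check_bins(bins)
    mh_values = [
        r.mh_len
        for r in classified
        if r.repair_class in MUTAGENIC_CLASSES and r.mh_len is not None
    ]
    if not mh_values:
        return {}
    hist: dict[str, float] = {}
    for label, lo, hi in bins:
        n = sum(1 for m in mh_values if lo <= m <= hi)
        if n:
            hist[label] = n / len(mh_values)
    return hist


def _check_bins(bins) -> None:
    edges = sorted(bins, key=lambda b: b[1])
    expect = 0
    for _, lo, hi in edges:
        if lo != expect:
            raise ValueError("microhomology bins must tile [0, inf) without gaps or overlap")
        expect = hi + 1 if hi != math.inf else None
        if expect is None:
            break
    else:
        raise ValueError("microhomology bins must extend to infinity")


def repair_score(test: ReporterCounts, control: ReporterCounts) -> float:
    """Dual-reporter repair score of a test population.

    (%NHEJ-positive / %SSA-positive) for the test population, normalized
    by the same ratio in the wildtype control; 1.0 means pathway balance
    indistinguishable from wildtype.
    """
    return test.ratio / control.ratio


def repair_score_se(test: ReporterCounts, control: ReporterCounts) -> float:
    """Delta-method standard error of the normalized repair score.

    The score is a product/quotient of four binomial proportions, so its
    relative variance is the sum of the four relative variances.
    """
    score = repair_score(test, control)
    rel_var = 0.0
    for k, n in (
        (test.nhej_positive, test.nhej_total),
        (test.ssa_positive, test.ssa_total),
        (control.nhej_positive, control.nhej_total),
        (control.ssa_positive, control.ssa_total),
    ):
        p = k / n
        if p in (0.0, 1.0):
            continue
        rel_var += (1 - p) / (p * n)
    return score * math.sqrt(rel_var)


def make_tornado(classified: Sequence[ClassifiedRead]) -> list[TornadoRecord]:
    """Mutagenic events sorted by size (largest first), deterministically.

    Secondary sort by deletion start then class name so ranks are
    reproducible; ranks are 0..n-1.
    """
    events = [r for r in classified if r.repair_class in MUTAGENIC_CLASSES]
    events.sort(
        key=lambda r: (-r.event_size, r.del_start if r.del_start is not None else -1,
                       r.repair_class.value)
    )
    return [
        TornadoRecord(r.repair_class, r.del_start, r.del_end, r.ins_len, r.event_size, rank)
        for rank, r in enumerate(events)
    ]


def plot_tornado(records: Sequence[TornadoRecord], ref_length: int, path=None):
    """Render a tornado plot: one horizontal bar per event, sorted by size."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    palette = {
        RepairClass.DELETION: "#1f77b4",
        RepairClass.INSERTION: "#2ca02c",
        RepairClass.DELINS: "#d62728",
        RepairClass.TANDEM_DUPLICATION: "#9467bd",
        RepairClass.COMPOUND_TD: "#8c564b",
    }
    fig, ax = plt.subplots(figsize=(6, max(2, len(records) * 0.02)))
    for rec in records:
        if rec.del_start is not None:
            x, w = rec.del_start, max(rec.del_end - rec.del_start, 1)
        else:
            x, w = ref_length / 2 - rec.ins_len / 2, max(rec.ins_len, 1)
        ax.barh(rec.rank, w, left=x, height=1.0, color=palette.get(rec.repair_class, "grey"))
    ax.set_xlim(0, ref_length)
    ax.invert_yaxis()
    ax.set_xlabel("amplicon position (bp)")
    ax.set_ylabel("events (sorted by size)")
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


def summarize_replicates(summaries: Sequence[RepairSummary]) -> dict:
    """Replicate-level mean and SEM of the mutagenic fraction."""
    import numpy as np

    fr = np.array([s.mutagenic_fraction for s in summaries], dtype=float)
    sem = float(fr.std(ddof=1) / math.sqrt(len(fr))) if len(fr) > 1 else float("nan")
    return {"n_replicates": len(fr), "mean_mutagenic_fraction": float(fr.mean()), "sem": sem}
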