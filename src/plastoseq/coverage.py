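"""Per-base depth profiling and the coverage statistics built on it.

Depth is the number of uniquely mapped reads covering each genomic base
position; every statistic here (covered fraction, CDS vs NonCDS depth
distributions, strand coverage, unmapped-region spectra) is computed from one
``DepthProfile`` so log2 summaries and log10 plotting tracks share a single
source of truth. "Covered" means depth >= 1. Zero-depth positions are counted
in covered fractions but excluded from log-scale distributions (log of zero
is undefined); they are reported separately per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genome import CODING, Feature, Plastome, classify_positions
from .mapping import AlignmentSet


@dataclass
class DepthProfile:
    """Per-base read depth; when unstranded, ``depth_fwd`` holds combined depth."""

    depth_fwd: np.ndarray
    depth_rev: np.ndarray
    stranded: bool

    @property
    def length(self) -> int:
        return self.depth_fwd.size

    def combined(self) -> np.ndarray:
        return self.depth_fwd + self.depth_rev if self.stranded else self.depth_fwd

    def total_bases(self) -> int:
        return int(self.depth_fwd.sum() + self.depth_rev.sum())


def compute_depth(alignments: AlignmentSet, genome_length: int,
                  stranded: bool = False) -> DepthProfile:
    """Accumulate per-base depth from alignments, wrap-aware.

    Each alignment increments every position of its footprint on its strand
    (or the combined track when ``stranded=False``). The profile conserves
    bases: total depth equals the sum of aligned read lengths.
    """
    L = genome_length
    tracks = {"+": np.zeros(L + 1, dtype=np.int64), "-": np.zeros(L + 1, dtype=np.int64)}
    for a in alignments.alignments:
        if not (0 <= a.position < L):
            raise ValueError(f"alignment at {a.position} outside [0, {L})")
        d = tracks[a.strand if stranded else "+"]
        e = a.position + a.length
        if e <= L:
            d[a.position] += 1
            d[e] -= 1
        else:
            d[a.position] += 1
            d[L] -= 1
            d[0] += 1
            d[e - L] -= 1
    fwd = np.cumsum(tracks["+"][:-1])
    rev = np.cumsum(tracks["-"][:-1])
    return DepthProfile(depth_fwd=fwd, depth_rev=rev, stranded=stranded)


def coverage_fraction(profile: DepthProfile, mask: Optional[np.ndarray] = None) -> float:
    """Fraction of (non-masked) positions with depth >= 1.

    ``mask`` is a boolean array marking positions to exclude (e.g. the repeat
    mask); masking the whole genome is an error.
    """
    depth = profile.combined()
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.all():
            raise ValueError("mask covers the whole genome")
        depth = depth[~mask]
    return float((depth >= 1).mean())


@dataclass
class ClassDepthStats:
    """Depth-distribution summary for one position class (CDS or NonCDS)."""

    n_positions: int
    n_zero: int
    depths: np.ndarray                 # depths of positions with depth >= 1
    log2_summary: dict = field(default_factory=dict)


def _log_summary(depths: np.ndarray, log_base: float = 2.0) -> dict:
    if depths.size == 0:
        return {"median": None, "q1": None, "q3": None, "p5": None, "p95": None,
                "n_outliers": 0}
    logd = np.log(depths) / np.log(log_base)
    q1, med, q3, p5, p95 = np.quantile(logd, [0.25, 0.5, 0.75, 0.05, 0.95])
    n_out = int(((logd < p5) | (logd > p95)).sum())
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "p5": float(p5), "p95": float(p95), "n_outliers": n_out}


def per_class_depth_stats(profile: DepthProfile, plastome: Plastome) -> dict[str, ClassDepthStats]:
    """Depth distributions for coding (CDS) vs non-coding (NonCDS) positions.

    CDS covers protein-coding, tRNA and rRNA genes; NonCDS covers intergenic
    space and introns. Summaries (median, quartiles, 5th/95th quantiles) are
    on log2(depth) of positions with depth >= 1; zero-depth positions are
    tallied separately.
    """
    classes = classify_positions(plastome)
    depth = profile.combined()
    out: dict[str, ClassDepthStats] = {}
    for label, sel in (("CDS", classes == CODING), ("NonCDS", classes != CODING)):
        d = depth[sel]
        pos = d[d >= 1]
        out[label] = ClassDepthStats(n_positions=int(sel.sum()), n_zero=int((d == 0).sum()),
                                     depths=pos, log2_summary=_log_summary(pos))
    return out


def log10_track(profile: DepthProfile) -> np.ndarray:
    """log10(depth) plotting track; zero-depth positions are NaN."""
    depth = profile.combined().astype(float)
    with np.errstate(divide="ignore"):
        track = np.log10(depth)
    track[depth == 0] = np.nan
    return track


def unmapped_regions(profile: DepthProfile) -> tuple[list[tuple[int, int]], dict[str, int]]:
    """Maximal zero-depth intervals and their length histogram (<30 / >=30 bp).

    Intervals are reported in linear coordinates [0, L); a gap spanning the
    circular origin appears as two intervals.
    """
    zero = profile.combined() == 0
    if not zero.any():
        return [], {"lt30": 0, "ge30": 0}
    padded = np.concatenate([[False], zero, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    intervals = [(int(s), int(e)) for s, e in zip(starts, ends)]
    hist = {"lt30": sum(1 for s, e in intervals if e - s < 30),
            "ge30": sum(1 for s, e in intervals if e - s >= 30)}
    return intervals, hist


@dataclass
class StrandCoverage:
    fwd_fraction: float
    rev_fraction: float
    per_class: dict


def strand_coverage(profile: DepthProfile, plastome: Optional[Plastome] = None) -> StrandCoverage:
    """Per-strand covered fractions (and per-class stats when annotation given)."""
    if not profile.stranded:
        raise ValueError("strand_coverage requires a stranded profile")
    fwd = float((profile.depth_fwd >= 1).mean())
    rev = float((profile.depth_rev >= 1).mean())
    per_class = {}
    if plastome is not None:
        for name, arr in (("fwd", profile.depth_fwd), ("rev", profile.depth_rev)):
            sub = DepthProfile(depth_fwd=arr, depth_rev=np.zeros_like(arr), stranded=False)
            per_class[name] = {k: v.log2_summary for k, v in per_class_depth_stats(sub, plastome).items()}
    return StrandCoverage(fwd_fraction=fwd, rev_fraction=rev, per_class=per_class)


def antisense_depth(profile: DepthProfile, feature: Feature) -> np.ndarray:
    """Depth over a feature on the strand opposite its annotated strand."""
    if not profile.stranded:
        raise ValueError("antisense depth requires a stranded profile")
    track = profile.depth_rev if feature.strand == "+" else profile.depth_fwd
    return track[feature.start:feature.end]


@dataclass
class CoverageReport:
    covered_fraction: float
    covered_fraction_masked: Optional[float]
    per_class: dict
    unmapped_intervals: list
    unmapped_histogram: dict
    strand_covered_fractions: Optional[tuple[float, float]]
    mapped_read_proportion: Optional[float]

    def to_dict(self) -> dict:
        return {
            "covered_fraction": self.covered_fraction,
            "covered_fraction_masked": self.covered_fraction_masked,
            "per_class": {k: {"n_positions": v.n_positions, "n_zero": v.n_zero,
                              "log2_summary": v.log2_summary}
                          for k, v in self.per_class.items()},
            "unmapped_intervals": self.unmapped_intervals,
            "unmapped_histogram": self.unmapped_histogram,
            "strand_covered_fractions": self.strand_covered_fractions,
            "mapped_read_proportion": self.mapped_read_proportion,
        }


def summarize_coverage(profile: DepthProfile, plastome: Plastome,
                       alignments: Optional[AlignmentSet] = None) -> CoverageReport:
    """Build the full coverage report from one depth profile."""
    mask = plastome.repeat_mask_array()
    masked = coverage_fraction(profile, mask) if mask.any() else None
    intervals, hist = unmapped_regions(profile)
    strands = None
    if profile.stranded:
        sc = strand_coverage(profile)
        strands = (sc.fwd_fraction, sc.rev_fraction)
    proportion = None
    if alignments is not None and alignments.n_input_reads:
        proportion = alignments.n_mapped / alignments.n_input_reads
    return CoverageReport(
        covered_fraction=coverage_fraction(profile),
        covered_fraction_masked=masked,
        per_class=per_class_depth_stats(profile, plastome),
        unmapped_intervals=intervals,
        unmapped_histogram=hist,
        strand_covered_fractions=strands,
        mapped_read_proportion=proportion,
    )


def plot_depth_track(profile: DepthProfile, plastome: Plastome, path) -> None:
    """Linear log10 depth track with gene positions, written as PNG/SVG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(12, 3))
    ax.plot(log10_track(profile), lw=0.5, color="black")
    for f in plastome.features:
        if f.feature_class.value in ("CDS", "tRNA", "rRNA"):
            ax.axvspan(f.start, f.end, color="tab:green", alpha=0.15, lw=0)
    ax.set_xlabel("genome position (bp)")
    ax.set_ylabel("log10 depth")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
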