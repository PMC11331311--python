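"""Runs-of-homozygosity calling and the per-SNP autozygosity track.

The caller is a sliding-window scan in the style of array-era ROH
tools: a fixed-size SNP window slides one SNP at a time; windows with at
most ``window_het_max`` heterozygous and ``window_missing_max`` missing
calls count as homozygous; a SNP is eligible when at least
``window_hit_threshold`` of the full windows containing it are
homozygous; maximal runs of eligible SNPs, split at large physical gaps,
become segments and are kept if they satisfy SNP-count, length and
density thresholds.  Only full windows are formed — no truncated windows
at chromosome ends — and the per-SNP hit fraction is taken over the full
windows that contain the SNP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import MISSING, GenotypeMatrix

__all__ = ["ROHParams", "ROHSegment", "detect_roh", "autozygosity", "roh_summary"]


@dataclass(frozen=True)
class ROHParams:
    """Sliding-window ROH thresholds.

    Defaults are the conventional ones for this family of callers, with
    the scanning window widened to 100 SNPs for sequence-density data:
    at most 1 heterozygote and 5 missing calls per window, a 5% window
    hit threshold, and segment minima of 100 SNPs and 1,000 kb with at
    most 50 kb per SNP and no internal gap above 1,000 kb.
    """

    window_snp: int = 100
    window_het_max: int = 1
    window_missing_max: int = 5
    window_hit_threshold: float = 0.05
    min_snp: int = 100
    min_length_kb: float = 1000.0
    max_inverse_density: float = 50.0  # kb per SNP
    max_internal_gap_kb: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 < self.window_hit_threshold <= 1:
            raise ValueError("window_hit_threshold must be in (0, 1]")
        for name in ("window_snp", "window_het_max", "window_missing_max",
                     "min_snp", "min_length_kb", "max_inverse_density",
                     "max_internal_gap_kb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ROHSegment:
    individual: str
    chrom: str
    start: int
    end: int
    n_snps: int

    @property
    def length_kb(self) -> float:
        return (self.end - self.start + 1) / 1000.0


def _window_sums(x: np.ndarray, w: int) -> np.ndarray:
    """Sliding sums of width w along axis 1 (full windows only)."""
    c = np.cumsum(x, axis=1, dtype=np.int32)
    c = np.concatenate([np.zeros((x.shape[0], 1), dtype=np.int32), c], axis=1)
    return c[:, w:] - c[:, :-w]


def detect_roh(g: GenotypeMatrix, params: ROHParams = ROHParams()) -> list[ROHSegment]:
    """Call ROH segments for every individual and chromosome."""
    segments: list[ROHSegment] = []
    for chrom in pd.unique(g.chrom):
        cols = np.flatnonzero(g.chrom == chrom)
        if len(cols) < params.window_snp:
            continue  # chromosome shorter than the scanning window: no calls
        geno = g.genotypes[:, cols]
        pos = g.positions[cols]
        eligible = _eligible_matrix(geno, params)
        for i in range(g.n_individuals):
            for s, e in _runs(eligible[i]):
                for s2, e2 in _split_gaps(pos, s, e, params.max_internal_gap_kb):
                    n_snps = e2 - s2 + 1
                    length_kb = (pos[e2] - pos[s2] + 1) / 1000.0
                    if (
                        n_snps >= params.min_snp
                        and length_kb >= params.min_length_kb
                        and length_kb / n_snps <= params.max_inverse_density
                    ):
                        segments.append(
                            ROHSegment(g.samples[i], str(chrom),
                                       int(pos[s2]), int(pos[e2]), n_snps)
                        )
    return segments


def _eligible_matrix(geno: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean (n_ind, n_snps): SNP eligible by the window hit fraction."""
    w = params.window_snp
    n_snps = geno.shape[1]
    het = (geno == 1).astype(np.int8)
    miss = (geno == MISSING).astype(np.int8)
    hom_win = (
        (_window_sums(het, w) <= params.window_het_max)
        & (_window_sums(miss, w) <= params.window_missing_max)
    )
    n_win = n_snps - w + 1
    # windows containing SNP j start in [max(0, j-w+1), min(j, n_win-1)]
    j = np.arange(n_snps)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_win - 1)
    n_containing = hi - lo + 1
    c = np.cumsum(hom_win, axis=1, dtype=np.int32)
    c = np.concatenate([np.zeros((geno.shape[0], 1), dtype=np.int32), c], axis=1)
    hits = c[:, hi + 1] - c[:, lo]
    return hits / n_containing >= params.window_hit_threshold


def _runs(mask: np.ndarray):
    """Maximal runs of True as (start_idx, end_idx) inclusive."""
    if not mask.any():
        return
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [len(mask) - 1]])
    yield from zip(starts, ends)


def _split_gaps(pos: np.ndarray, s: int, e: int, max_gap_kb: float):
    """Split [s, e] wherever an adjacent-SNP gap exceeds max_gap_kb."""
    if e == s:
        yield s, e
        return
    gaps = np.diff(pos[s:e + 1]) / 1000.0
    breaks = np.flatnonzero(gaps > max_gap_kb)
    prev = s
    for b in breaks:
        yield prev, s + b
        prev = s + b + 1
    yield prev, e


def autozygosity(
    segments: list[ROHSegment],
    chrom: np.ndarray,
    positions: np.ndarray,
    n_individuals: int,
) -> np.ndarray:
    """Per-SNP proportion of individuals whose ROH cover that position.

    Overlapping segments of one individual count once (distinct-individual
    rule); values lie in [0, 1].
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    chrom = np.asarray(chrom, dtype=object)
    positions = np.asarray(positions)
    covered: dict[str, np.ndarray] = {}
    for seg in segments:
        track = covered.setdefault(seg.individual, np.zeros(len(positions), dtype=bool))
        on_chrom = chrom == seg.chrom
        track |= on_chrom & (positions >= seg.start) & (positions <= seg.end)
    count = np.zeros(len(positions), dtype=float)
    for track in covered.values():
        count += track
    return count / n_individuals


_LENGTH_CLASSES_MB = [(1, 5), (5, 10), (10, 15), (15, 20), (20, 25), (25, 30)]


def roh_summary(
    segments: list[ROHSegment],
    n_individuals: int | None = None,
    sd_single: float = float("nan"),
) -> dict:
    """Descriptive summary: per-animal counts, length stats, length classes.

    Length classes are half-open [a, b) in Mb plus an open-ended >30 Mb
    class, so they partition the length axis.  ``sd_single`` is reported
    as the SD when only one value exists (NaN by default, 0 if preferred).
    """
    out: dict = {"n_segments": len(segments)}
    if not segments:
        counts = {f"roh_{a}_{b}_mb": 0 for a, b in _LENGTH_CLASSES_MB}
        counts["roh_gt30_mb"] = 0
        out.update({"per_animal": {"mean": 0.0, "sd": 0.0, "min": 0, "max": 0},
                    "length_kb": {"mean": 0.0, "sd": 0.0, "median": 0.0,
                                  "min": 0.0, "max": 0.0},
                    "length_classes": counts,
                    "pct_animals_with_roh": 0.0 if n_individuals else float("nan")})
        return out

    per_animal = pd.Series([s.individual for s in segments]).value_counts()
    lengths_kb = np.array([s.length_kb for s in segments])

    def _sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if len(x) > 1 else sd_single

    out["per_animal"] = {
        "mean": float(per_animal.mean()),
        "sd": _sd(per_animal.to_numpy(dtype=float)),
        "min": int(per_animal.min()),
        "max": int(per_animal.max()),
    }
    out["length_kb"] = {
        "mean": float(lengths_kb.mean()),
        "sd": _sd(lengths_kb),
        "median": float(np.median(lengths_kb)),
        "min": float(lengths_kb.min()),
        "max": float(lengths_kb.max()),
    }
    mb = lengths_kb / 1000.0
    classes = {
        f"roh_{a}_{b}_mb": int(((mb >= a) & (mb < b)).sum())
        for a, b in _LENGTH_CLASSES_MB
    }
    classes["roh_gt30_mb"] = int((mb >= 30).sum())
    out["length_classes"] = classes
    if n_individuals:
        out["pct_animals_with_roh"] = 100.0 * per_animal.size / n_individuals
    else:
        out["pct_animals_with_roh"] = float("nan")
    return out


def segments_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.individual, s.chrom, s.start, s.end, s.n_snps, s.length_kb)
         for s in segments],
        columns=["iid", "chrom", "start", "end", "n_snps", "kb"],
    )
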