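"""Input preparation for clone copy-number inference.

Covers the path from binned read counts to solver-ready fractional copy
numbers: bin-to-segment aggregation, depth-to-copy-number scaling, statistical
flagging of subclonal and allelically imbalanced segments, allele rebalancing
of balanced subclonal segments, and the eligibility rule restricting where
homozygous deletions may be called.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CloneProportions, FractionalCN, SegmentTable, ValidationError
from .tree import CloneTree

__all__ = [
    "aggregate_bins",
    "scale_depth_to_fractional",
    "classify_clonality",
    "flag_allelic_imbalance",
    "rebalance_alleles",
    "homdel_eligibility",
    "HomDelEligibility",
]

logger = logging.getLogger(__name__)

CLONALITY_P = 1e-4   # one-sample test against the nearest integer
IMBALANCE_P = 1e-3   # two-sample test between alleles
HOMDEL_MAX_LEN = 50_000_000  # bp; longer segments can never be (0,0)
HOMDEL_THRESHOLD = 1.0       # fractional CN below which a sample supports (0,0)


def aggregate_bins(bins: pd.DataFrame, segments: SegmentTable) -> pd.DataFrame:
    """Average bin read depth and BAF over the bins overlapping each segment.

    ``bins`` columns: ``chrom``, ``start``, ``end``, ``sample``, ``depth``,
    ``baf``.  A bin contributes, unweighted, to every segment it overlaps by
    at least one base pair.  Returns a frame with one row per (segment,
    sample) and columns ``depth`` (R) and ``baf`` (B).
    """
    required = {"chrom", "start", "end", "sample", "depth", "baf"}
    if not required <= set(bins.columns):
        raise ValidationError(f"bin table missing columns {sorted(required - set(bins.columns))}")
    if (bins["depth"] < 0).any():
        raise ValidationError("negative read depth in bin table")
    if ((bins["baf"] < 0) | (bins["baf"] > 1)).any():
        raise ValidationError("BAF outside [0, 1] in bin table")

    rows = []
    for seg in segments.frame.itertuples(index=False):
        hits = bins[
            (bins["chrom"].astype(str) == str(seg.chrom))
            & (bins["start"] <= seg.end)
            & (bins["end"] >= seg.start)
        ]
        if hits.empty:
            raise ValidationError(f"segment {seg.segment!r} overlaps no bins")
        for sample, grp in hits.groupby("sample", sort=True):
            rows.append(
                {
                    "segment": seg.segment,
                    "sample": sample,
                    "depth": grp["depth"].mean(),
                    "baf": grp["baf"].mean(),
                }
            )
    return pd.DataFrame(rows)


def scale_depth_to_fractional(
    aggregated: pd.DataFrame,
    reference_total: pd.DataFrame,
    noise_sd: float = 0.1,
    z: float = 1.96,
) -> pd.DataFrame:
    """Scale mean segment depths to total fractional copy numbers.

    A per-(segment, sample) scaling factor ``gamma = F_ref / R`` is averaged
    over segments within each sample, and the per-sample mean is applied back
    to every depth: ``F = mean(gamma) * R``.  The total is then split by BAF:
    ``F_A = F * (1 - B)``, ``F_B = F * B``.

    ``reference_total`` columns: ``segment``, ``sample``, ``F`` (the reference
    total fractional copy number used to calibrate depth).  Returns a solver
    input frame with estimates and ``z * noise_sd`` interval bounds.
    """
    df = aggregated.merge(reference_total, on=["segment", "sample"], validate="1:1")
    if (df["depth"] <= 0).any():
        bad = df.loc[df["depth"] <= 0, "segment"].tolist()
        raise ValidationError(f"zero read depth in segments {bad}; cannot derive scaling")
    df["gamma"] = df["F"] / df["depth"]
    gamma_bar = df.groupby("sample")["gamma"].transform("mean")
    total = gamma_bar * df["depth"]
    out = pd.DataFrame(
        {
            "segment": df["segment"],
            "sample": df["sample"],
            "fA": total * (1.0 - df["baf"]),
            "fB": total * df["baf"],
        }
    )
    half = z * noise_sd
    for allele in ("fA", "fB"):
        out[f"{allele}_lo"] = np.maximum(out[allele] - half, 0.0)
        out[f"{allele}_hi"] = out[allele] + half
    return out


def _nearest_int(x: np.ndarray | float) -> np.ndarray:
    return np.rint(np.asarray(x, dtype=float))


def classify_clonality(
    fractional: FractionalCN,
    replicates: pd.DataFrame | None,
    p_threshold: float = CLONALITY_P,
) -> pd.DataFrame:
    """Flag segments whose fractional CN is significantly non-integer.

    ``replicates`` columns: ``segment``, ``sample``, ``allele`` (A/B),
    ``value`` -- within-segment replicate estimates (e.g. SNP-level).  A
    segment is subclonal when, for either allele in any sample, a one-sample
    t-test of the replicates against their nearest integer rejects at
    ``p < p_threshold``.  Segments without >=2 replicates anywhere are
    untestable and treated as clonal.
    """
    rows = []
    for seg in fractional.segments:
        subclonal = False
        testable = False
        if replicates is not None:
            reps = replicates[replicates["segment"].astype(str) == seg]
            for (_, _), grp in reps.groupby(["sample", "allele"]):
                vals = grp["value"].to_numpy(dtype=float)
                if len(vals) < 2 or np.allclose(vals, vals[0]):
                    continue
                testable = True
                target = float(_nearest_int(vals.mean()))
                pval = stats.ttest_1samp(vals, target).pvalue
                if pval < p_threshold:
                    subclonal = True
                    break
        if not testable:
            logger.debug("segment %s untestable for clonality; treated as clonal", seg)
        rows.append({"segment": seg, "subclonal": subclonal, "testable": testable})
    return pd.DataFrame(rows)


def flag_allelic_imbalance(
    replicates: pd.DataFrame,
    segments: list[str] | None = None,
    p_threshold: float = IMBALANCE_P,
) -> pd.DataFrame:
    """Flag segments whose two alleles differ significantly in >=1 sample.

    Uses a two-sample t-test between allele A and allele B replicate values
    per sample.  Segments without enough replicates are untestable and treated
    as balanced.
    """
    if segments is None:
        segments = list(dict.fromkeys(replicates["segment"].astype(str)))
    rows = []
    for seg in segments:
        reps = replicates[replicates["segment"].astype(str) == str(seg)]
        imbalanced = False
        testable = False
        for _, grp in reps.groupby("sample"):
            a = grp.loc[grp["allele"] == "A", "value"].to_numpy(dtype=float)
            b = grp.loc[grp["allele"] == "B", "value"].to_numpy(dtype=float)
            if len(a) < 2 or len(b) < 2:
                continue
            if np.allclose(a, a[0]) and np.allclose(b, b[0]):
                if not np.isclose(a[0], b[0]):
                    testable = imbalanced = True
                    break
                testable = True
                continue
            testable = True
            pval = stats.ttest_ind(a, b, equal_var=False).pvalue
            if pval < p_threshold:
                imbalanced = True
                break
        rows.append({"segment": seg, "imbalanced": imbalanced, "testable": testable})
    return pd.DataFrame(rows)


def rebalance_alleles(fractional: FractionalCN, flags: pd.DataFrame) -> FractionalCN:
    """Reassign allele values of subclonal, allelically balanced segments.

    For each flagged segment (``subclonal`` and not ``imbalanced``), per
    sample: if both allele estimates exceed their nearest integers, allele B
    is snapped to its nearest integer and allele A absorbs the remainder; if
    both are below, allele A is snapped and allele B absorbs the remainder.
    The total ``fA + fB`` is conserved exactly.  Mixed segments (one allele
    above, one below) are left unchanged and logged.  Bounds are shifted with
    their estimate so interval widths are preserved.
    """
    balanced = (
        ~flags["imbalanced"].astype(bool)
        if "imbalanced" in flags.columns
        else pd.Series(True, index=flags.index)
    )
    flagged = set(flags.loc[flags["subclonal"].astype(bool) & balanced, "segment"].astype(str))
    est = fractional.est.copy()
    lo = fractional.lo.copy()
    hi = fractional.hi.copy()
    for i, seg in enumerate(fractional.segments):
        if seg not in flagged:
            continue
        for r in range(len(fractional.samples)):
            fa, fb = est[i, r]
            na, nb = _nearest_int(fa), _nearest_int(fb)
            total = fa + fb
            if fa > na and fb > nb:
                new_b, new_a = nb, na + (total - na - nb)
            elif fa < na and fb < nb:
                new_a, new_b = na, nb + (total - na - nb)
            else:
                logger.debug(
                    "segment %s sample %s: alleles straddle their integers; left unchanged",
                    seg,
                    fractional.samples[r],
                )
                continue
            for a_idx, (old, new) in enumerate([(fa, new_a), (fb, new_b)]):
                shift = new - old
                est[i, r, a_idx] = new
                lo[i, r, a_idx] = max(lo[i, r, a_idx] + shift, 0.0)
                hi[i, r, a_idx] = hi[i, r, a_idx] + shift
    return FractionalCN(fractional.segments, fractional.samples, est, lo, hi)


@dataclass(frozen=True)
class HomDelEligibility:
    """Boolean eligibility of the (0,0) state per segment and tumour clone."""

    segments: tuple[str, ...]
    clones: tuple[str, ...]
    eligible: np.ndarray  # (m, n_tumour_clones) bool

    def for_segment(self, segment: str) -> dict[str, bool]:
        i = self.segments.index(segment)
        return {c: bool(self.eligible[i, j]) for j, c in enumerate(self.clones)}


def homdel_eligibility(
    tree: CloneTree,
    proportions: CloneProportions,
    fractional: FractionalCN,
    segments: SegmentTable,
    h: float = HOMDEL_THRESHOLD,
    max_len: int = HOMDEL_MAX_LEN,
) -> HomDelEligibility:
    """Where may a clone carry a homozygous deletion.

    A clone may be (0,0) in a segment only if the segment is shorter than
    ``max_len`` and the clone, or one of its descendants, is present in some
    sample whose fractional copy number is below ``h`` on both alleles.
    """
    seg_order = [fractional.segments.index(s) for s in segments.segments]
    lengths = segments.lengths
    clones = tree.tumour_clones
    u = proportions.for_clones(clones)
    low_both = (fractional.est[..., 0] < h) & (fractional.est[..., 1] < h)  # (m, k)
    low_both = low_both[seg_order]
    eligible = np.zeros((len(seg_order), len(clones)), dtype=bool)
    for j, clone in enumerate(clones):
        group = [clone] + tree.descendants(clone)
        idx = [clones.index(c) for c in group]
        present = (u[idx] > 0).any(axis=0)  # (k,)
        support = (low_both & present[None, :]).any(axis=1)  # (m,)
        eligible[:, j] = support & (lengths < max_len)
    return HomDelEligibility(tuple(segments.segments), tuple(clones), eligible)
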