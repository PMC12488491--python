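"""Core domain types for clone copy-number deconvolution.

Conventions used throughout the package:

* Genomic coordinates are 1-based and inclusive; a segment of ``start==end``
  has length 1 bp.
* Allele axes are ordered ``(A, B)`` everywhere; index 0 is allele A.
* Fractional copy numbers are on the scale of the clone mixture
  ``f = sum_i c_i * u_i`` over tumour clones, i.e. the cancer-cell
  contribution to the bulk average (the quantity estimated by allele-specific
  SCNA callers after purity correction).
* Rounding to "nearest integer" uses round-half-to-even in every module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import CloneTree, NORMAL_CLONE

__all__ = [
    "SegmentTable",
    "CloneProportions",
    "FractionalCN",
    "CloneCNProfile",
    "ValidationError",
    "mixture_fractional",
    "simple_model_baseline",
    "chrom_sort_key",
]

PROPORTION_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when an input object violates a documented invariant."""


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural ordering for chromosome names: 1..22 < X < Y < others."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.isdigit():
        return (int(c), "")
    order = {"X": 100, "Y": 101, "MT": 102, "M": 102}
    return (order.get(c.upper(), 200), c)


@dataclass(frozen=True)
class SegmentTable:
    """Non-overlapping genomic segments in stable (chromosome, start) order.

    ``frame`` columns: ``segment``, ``chrom``, ``start``, ``end`` and
    optionally ``arm``.  Lengths are ``end - start + 1`` base pairs.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        required = {"segment", "chrom", "start", "end"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"segment table missing columns {sorted(missing)}")
        df = self.frame.copy()
        df["segment"] = df["segment"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        if df["segment"].duplicated().any():
            dups = df.loc[df["segment"].duplicated(), "segment"].tolist()
            raise ValidationError(f"duplicate segment IDs: {dups}")
        if (df["start"] > df["end"]).any():
            bad = df.loc[df["start"] > df["end"], "segment"].tolist()
            raise ValidationError(f"segments with start > end: {bad}")
        df["_key"] = df["chrom"].map(chrom_sort_key)
        df = df.sort_values(["_key", "start"], kind="mergesort").drop(columns="_key")
        for chrom, grp in df.groupby("chrom", sort=False):
            ends = grp["end"].to_numpy()
            starts = grp["start"].to_numpy()
            if (starts[1:] <= ends[:-1]).any():
                raise ValidationError(f"overlapping segments on chromosome {chrom}")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    @property
    def segments(self) -> list[str]:
        return self.frame["segment"].tolist()

    @property
    def lengths(self) -> np.ndarray:
        """Segment lengths in bp, in table order."""
        return (self.frame["end"] - self.frame["start"] + 1).to_numpy(dtype=float)

    @property
    def chroms(self) -> np.ndarray:
        return self.frame["chrom"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class CloneProportions:
    """Clone fractions ``u[i, r]`` per sample, normal clone included.

    Each sample column sums to one; purity of a sample is ``1 - u[normal]``.
    """

    clones: tuple[str, ...]
    samples: tuple[str, ...]
    u: np.ndarray  # shape (n_clones, n_samples)

    def __post_init__(self):
        object.__setattr__(self, "clones", tuple(str(c) for c in self.clones))
        object.__setattr__(self, "samples", tuple(str(s) for s in self.samples))
        u = np.asarray(self.u, dtype=float)
        object.__setattr__(self, "u", u)
        if u.shape != (len(self.clones), len(self.samples)):
            raise ValidationError(
                f"proportion matrix shape {u.shape} does not match "
                f"{len(self.clones)} clones x {len(self.samples)} samples"
            )
        if NORMAL_CLONE not in self.clones:
            raise ValidationError(f"normal clone {NORMAL_CLONE!r} missing from proportions")
        if (u < -PROPORTION_TOL).any():
            raise ValidationError("negative clone proportions")
        sums = u.sum(axis=0)
        bad = np.abs(sums - 1.0) > PROPORTION_TOL
        if bad.any():
            off = {self.samples[i]: float(sums[i]) for i in np.flatnonzero(bad)}
            raise ValidationError(f"clone proportions do not sum to 1 in samples: {off}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CloneProportions":
        """Build from a long table with columns ``clone``, ``sample``, ``proportion``."""
        pivot = df.pivot_table(
            index="clone", columns="sample", values="proportion", fill_value=0.0, sort=False
        )
        return cls(tuple(pivot.index), tuple(pivot.columns), pivot.to_numpy(dtype=float))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"clone": c, "sample": s, "proportion": self.u[i, r]}
            for i, c in enumerate(self.clones)
            for r, s in enumerate(self.samples)
        ]
        return pd.DataFrame(rows)

    @property
    def purity(self) -> np.ndarray:
        """Per-sample tumour purity ``1 - u[normal]``."""
        return 1.0 - self.u[self.clones.index(NORMAL_CLONE)]

    def for_clones(self, clones: list[str]) -> np.ndarray:
        """Proportion matrix rows reordered for the given clone list."""
        idx = []
        for c in clones:
            if c not in self.clones:
                raise ValidationError(f"clone {c!r} has no proportions")
            idx.append(self.clones.index(c))
        return self.u[idx]


@dataclass(frozen=True)
class FractionalCN:
    """Observed allele-specific fractional copy numbers with interval bounds.

    Arrays are shaped ``(n_segments, n_samples, 2)`` with the last axis being
    the allele (A, B).  ``lo <= est <= hi`` element-wise and all values >= 0.
    """

    segments: tuple[str, ...]
    samples: tuple[str, ...]
    est: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(str(s) for s in self.segments))
        object.__setattr__(self, "samples", tuple(str(s) for s in self.samples))
        shape = (len(self.segments), len(self.samples), 2)
        for name in ("est", "lo", "hi"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != shape:
                raise ValidationError(f"{name} has shape {arr.shape}, expected {shape}")
        if (self.est < 0).any() or (self.lo < 0).any():
            raise ValidationError("fractional copy numbers must be non-negative")
        bad = (self.lo > self.est + 1e-12) | (self.est > self.hi + 1e-12)
        if bad.any():
            s_idx, r_idx, a_idx = np.unravel_index(np.argmax(bad), bad.shape)
            raise ValidationError(
                "bounds must satisfy lo <= estimate <= hi; violated for segment "
                f"{self.segments[s_idx]!r}, sample {self.samples[r_idx]!r}, "
                f"allele {'AB'[a_idx]}"
            )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FractionalCN":
        cols = ["fA", "fA_lo", "fA_hi", "fB", "fB_lo", "fB_hi"]
        missing = {"segment", "sample", *cols} - set(df.columns)
        if missing:
            raise ValidationError(f"fractional CN table missing columns {sorted(missing)}")
        segs = list(dict.fromkeys(df["segment"].astype(str)))
        samps = list(dict.fromkeys(df["sample"].astype(str)))
        m, k = len(segs), len(samps)
        est = np.full((m, k, 2), np.nan)
        lo = np.full((m, k, 2), np.nan)
        hi = np.full((m, k, 2), np.nan)
        si = {s: i for i, s in enumerate(segs)}
        ri = {s: i for i, s in enumerate(samps)}
        for row in df.itertuples(index=False):
            i, r = si[str(row.segment)], ri[str(row.sample)]
            est[i, r] = (row.fA, row.fB)
            lo[i, r] = (row.fA_lo, row.fB_lo)
            hi[i, r] = (row.fA_hi, row.fB_hi)
        if np.isnan(est).any():
            i, r, _ = np.unravel_index(int(np.argmax(np.isnan(est))), est.shape)
            raise ValidationError(
                f"missing fractional CN for segment {segs[i]!r}, sample {samps[r]!r}"
            )
        return cls(tuple(segs), tuple(samps), est, lo, hi)

    def to_frame(self, segments: SegmentTable | None = None) -> pd.DataFrame:
        coords = None
        if segments is not None:
            coords = segments.frame.set_index("segment")
        rows = []
        for i, seg in enumerate(self.segments):
            for r, samp in enumerate(self.samples):
                row = {"segment": seg}
                if coords is not None:
                    row.update(
                        chrom=coords.loc[seg, "chrom"],
                        start=coords.loc[seg, "start"],
                        end=coords.loc[seg, "end"],
                    )
                row.update(
                    sample=samp,
                    fA=self.est[i, r, 0],
                    fA_lo=self.lo[i, r, 0],
                    fA_hi=self.hi[i, r, 0],
                    fB=self.est[i, r, 1],
                    fB_lo=self.lo[i, r, 1],
                    fB_hi=self.hi[i, r, 1],
                )
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CloneCNProfile:
    """Integer allele-specific copy numbers per segment and clone.

    ``cA`` and ``cB`` have shape ``(n_segments, n_clones)``; the normal clone
    is fixed at (1, 1) everywhere.
    """

    segments: tuple[str, ...]
    clones: tuple[str, ...]
    cA: np.ndarray
    cB: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(str(s) for s in self.segments))
        object.__setattr__(self, "clones", tuple(str(c) for c in self.clones))
        shape = (len(self.segments), len(self.clones))
        for name in ("cA", "cB"):
            arr = np.asarray(getattr(self, name))
            if not np.issubdtype(arr.dtype, np.integer):
                rounded = np.rint(arr)
                if not np.allclose(arr, rounded, atol=1e-9):
                    raise ValidationError(f"{name} contains non-integer copy numbers")
                arr = rounded.astype(np.int64)
            arr = arr.astype(np.int64)
            object.__setattr__(self, name, arr)
            if arr.shape != shape:
                raise ValidationError(f"{name} has shape {arr.shape}, expected {shape}")
            if (arr < 0).any():
                raise ValidationError(f"{name} contains negative copy numbers")
        if NORMAL_CLONE in self.clones:
            j = self.clones.index(NORMAL_CLONE)
            if (self.cA[:, j] != 1).any() or (self.cB[:, j] != 1).any():
                raise ValidationError("normal clone must be (1,1) in every segment")

    def allele(self, which: str) -> np.ndarray:
        return self.cA if which == "A" else self.cB

    def clone_index(self, clone: str) -> int:
        try:
            return self.clones.index(clone)
        except ValueError:
            raise KeyError(f"clone {clone!r} not in profile") from None

    def column(self, clone: str) -> np.ndarray:
        """(m, 2) allele-specific copy numbers of one clone."""
        j = self.clone_index(clone)
        return np.stack([self.cA[:, j], self.cB[:, j]], axis=1)

    def reorder(self, segments: list[str], clones: list[str]) -> "CloneCNProfile":
        si = [self.segments.index(s) for s in segments]
        ci = [self.clone_index(c) for c in clones]
        return CloneCNProfile(
            tuple(segments), tuple(clones), self.cA[np.ix_(si, ci)], self.cB[np.ix_(si, ci)]
        )

    def to_frame(self, segments: SegmentTable | None = None) -> pd.DataFrame:
        coords = segments.frame.set_index("segment") if segments is not None else None
        rows = []
        for i, seg in enumerate(self.segments):
            for j, clone in enumerate(self.clones):
                row = {"segment": seg}
                if coords is not None:
                    row.update(
                        chrom=coords.loc[seg, "chrom"],
                        start=int(coords.loc[seg, "start"]),
                        end=int(coords.loc[seg, "end"]),
                    )
                row.update(clone=clone, cnA=int(self.cA[i, j]), cnB=int(self.cB[i, j]))
                rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mixture identity and the simple baseline
# ---------------------------------------------------------------------------

def mixture_fractional(
    profile: CloneCNProfile, proportions: CloneProportions
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted fractional copy numbers ``f = sum_i c_i u_i`` over tumour clones.

    Returns ``(fA, fB)`` arrays of shape ``(n_segments, n_samples)``.  The
    normal clone is excluded from the sum: observed fractional copy numbers
    are modelled as the cancer-cell mixture of integer clone states.
    """
    tumour = [c for c in profile.clones if c != NORMAL_CLONE]
    missing = set(tumour) - set(proportions.clones)
    if missing:
        raise ValidationError(f"clones without proportions: {sorted(missing)}")
    u = proportions.for_clones(tumour)  # (n, k)
    idx = [profile.clones.index(c) for c in tumour]
    fA = profile.cA[:, idx] @ u
    fB = profile.cB[:, idx] @ u
    return fA, fB


def _round_half_even(x: np.ndarray | float) -> np.ndarray:
    return np.rint(np.asarray(x, dtype=float)).astype(np.int64)


def simple_model_baseline(
    fractional: FractionalCN,
    proportions: CloneProportions,
    tree: CloneTree,
) -> CloneCNProfile:
    """Nearest-integer baseline: round the fractional CN of each clone's modal sample.

    For every tumour clone, take the sample in which the clone is most
    prevalent and round the observed allele-specific fractional copy number to
    the nearest integer (half-to-even).  Clones absent from every sample
    inherit the states of their closest ancestor with a value; if no ancestor
    has one, they take the states of their (single lineage of) children.
    """
    clones = [NORMAL_CLONE] + tree.tumour_clones
    m = len(fractional.segments)
    cA = np.full((m, len(clones)), -1, dtype=np.int64)
    cB = np.full((m, len(clones)), -1, dtype=np.int64)
    cA[:, 0] = 1
    cB[:, 0] = 1

    u = proportions.for_clones(tree.tumour_clones)
    for j, clone in enumerate(tree.tumour_clones, start=1):
        uj = u[j - 1]
        if uj.max() > 0:
            r = int(np.argmax(uj))
            cA[:, j] = _round_half_even(fractional.est[:, r, 0])
            cB[:, j] = _round_half_even(fractional.est[:, r, 1])

    col = {c: j for j, c in enumerate(clones)}
    # extinct clones: closest ancestor first (preorder guarantees ancestors done)
    for clone in tree.tumour_clones:
        j = col[clone]
        if cA[0, j] >= 0:
            continue
        for anc in tree.ancestors(clone):
            ja = col[anc]
            if anc != NORMAL_CLONE and cA[0, ja] >= 0:
                cA[:, j] = cA[:, ja]
                cB[:, j] = cB[:, ja]
                break
    # remaining gaps (no tumour ancestor with data): take states of children
    for clone in reversed(tree.tumour_clones):
        j = col[clone]
        if cA[0, j] >= 0:
            continue
        kids = [k for k in tree.children(clone) if cA[0, col[k]] >= 0]
        if not kids:
            raise ValidationError(
                f"clone {clone!r} has no prevalent sample, ancestor or child to copy from"
            )
        cA[:, j] = cA[:, col[kids[0]]]
        cB[:, j] = cB[:, col[kids[0]]]

    return CloneCNProfile(fractional.segments, tuple(clones), cA, cB)
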