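"""Synthetic multi-sample bulk tumours with known clone copy numbers.

The generator produces the full ground truth needed to exercise every other
module: a random clone tree with a diploid root, integer allele-specific
copy-number profiles built from interval gain/loss events (optionally with a
whole-genome doubling), per-sample clone proportions, and read-count-derived
observed fractional copy numbers.

Reads are modelled per segment and sample: the total read count is
``t ~ Poisson(f_all / rho * gamma)`` where ``f_all`` is the all-cell total
fractional copy number, ``rho`` the sample ploidy (length-weighted mean of
``f_all``) and ``gamma`` the expected coverage; the observed B-allele
frequency is ``Binomial(gamma, beta) / gamma`` with ``beta = y_all / f_all``.
Observed totals are rescaled as ``F = (t / gamma) * rho`` and split by the
observed BAF, then the constant normal-cell contribution is subtracted to
put the estimates on the tumour-mixture scale used by the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import CloneCNProfile, CloneProportions, FractionalCN, SegmentTable
from .tree import CloneTree, NORMAL_CLONE

__all__ = ["SimConfig", "GroundTruth", "simulate_tree_and_profile",
           "simulate_proportions", "draw_reads", "simulate_reads",
           "simulate_tumour", "export_truth"]

N_CHROMS = 22


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic tumour.

    Defaults follow the benchmark conditions of the method: expected coverage
    ``gamma = 1000``, Normal(0, 0.1) interval half-widths at z = 1.96, and
    clone/sample/segment counts in the ranges used for the simulated cohorts.
    Event counts per edge emulate a high truncal SCNA burden with sparser
    subclonal events, as seen in non-small cell lung cancer.
    """

    n_clones: int = 7
    n_samples: int = 3
    n_segments: int = 100
    truncal_events: float = 8.0       # Poisson mean on the root -> MRCA edge
    subclonal_events: float = 2.0     # Poisson mean on every other edge
    wgd_prob: float = 0.4             # probability of a truncal whole-genome doubling
    gain_prob: float = 0.5            # gains vs losses among interval events
    mean_run_length: float = 3.0      # segments affected by one interval event
    c_max: int = 8                    # hard ceiling on simulated copy numbers
    coverage: float = 1000.0          # gamma: expected read coverage per sample
    noise_sd: float = 0.1             # sd used to build interval bounds
    bound_z: float = 1.96
    purity_range: tuple[float, float] = (0.4, 0.9)
    dirichlet_alpha: float = 1.5
    min_clone_fraction: float = 0.05  # floor on present-clone tumour fractions
    detection_fraction: float = 0.1   # every clone reaches this fraction somewhere
    lineages_per_sample: tuple[int, int] = (1, 3)
    seed: int = 0

    def __post_init__(self):
        if self.n_clones < 1 or self.n_samples < 1 or self.n_segments < 1:
            raise ValueError("clone, sample and segment counts must be positive")
        if not (0 <= self.wgd_prob <= 1 and 0 <= self.gain_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity range must satisfy 0 < lo <= hi <= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows about one synthetic tumour."""

    config: SimConfig
    tree: CloneTree
    segments: SegmentTable
    profile: CloneCNProfile           # true integer clone copy numbers
    proportions: CloneProportions     # true clone fractions per sample
    fA: np.ndarray                    # tumour-mixture fractional CN, (m, k)
    fB: np.ndarray
    x_all: np.ndarray                 # all-cell fractional CN, allele A, (m, k)
    y_all: np.ndarray                 # allele B
    beta: np.ndarray                  # true BAF y_all / (x_all + y_all)
    rho: np.ndarray                   # per-sample ploidy (k,)


def _random_segments(rng: np.random.Generator, m: int) -> SegmentTable:
    """Random non-overlapping segments over 22 chromosomes with p/q arms."""
    chroms = np.sort(rng.integers(1, N_CHROMS + 1, size=m))
    rows = []
    by_chrom: dict[int, int] = {}
    for ch in chroms:
        by_chrom[ch] = by_chrom.get(ch, 0) + 1
    idx = 0
    for ch in sorted(by_chrom):
        count = by_chrom[ch]
        lengths = np.exp(rng.uniform(np.log(5e5), np.log(4e7), size=count))
        pos = 1
        for j, ln in enumerate(lengths):
            start = pos
            end = pos + int(ln)
            rows.append(
                {
                    "segment": f"seg{idx:04d}",
                    "chrom": str(ch),
                    "start": start,
                    "end": end,
                    "arm": "p" if j < count / 2 else "q",
                }
            )
            pos = end + 1
            idx += 1
    return SegmentTable(pd.DataFrame(rows))


def _random_tree(rng: np.random.Generator, n_clones: int) -> CloneTree:
    edges = [(NORMAL_CLONE, "clone1")]
    for i in range(2, n_clones + 1):
        parent = int(rng.integers(1, i))
        edges.append((f"clone{parent}", f"clone{i}"))
    return CloneTree(edges)


def simulate_tree_and_profile(config: SimConfig, rng: np.random.Generator | None = None):
    """Random clone tree plus an event-built true copy-number profile.

    Events are placed per edge as +/-1 changes over contiguous segment runs on
    one chromosome and one allele.  LOH persistence and the path sign-run
    bound hold by construction: an event skips any segment where applying it
    would regain a lost allele, exceed two sign runs on the path, go negative
    or exceed the simulated ceiling.  A whole-genome doubling, when drawn,
    doubles both alleles on the truncal edge.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    tree = _random_tree(rng, config.n_clones)
    segments = _random_segments(rng, config.n_segments)
    m = len(segments)
    chrom_of = segments.chroms
    clones = [NORMAL_CLONE] + tree.tumour_clones
    col = {c: j for j, c in enumerate(clones)}
    c = np.ones((m, len(clones), 2), dtype=np.int64)

    # per-path bookkeeping for the sign-run bound: last sign and run count
    sign = {NORMAL_CLONE: np.zeros((m, 2), dtype=np.int64)}
    runs = {NORMAL_CLONE: np.zeros((m, 2), dtype=np.int64)}
    wgd = rng.random() < config.wgd_prob

    for clone in tree.tumour_clones:
        parent = tree.parent(clone)
        j, pj = col[clone], col[parent]
        c[:, j] = c[:, pj]
        sign_c = sign[parent].copy()
        runs_c = runs[parent].copy()
        truncal = parent == NORMAL_CLONE
        n_events = rng.poisson(config.truncal_events if truncal else config.subclonal_events)
        if truncal and wgd:
            doubled = c[:, j] > 0
            c[:, j][doubled] *= 2
            new_run = (sign_c != 1) & doubled
            runs_c += new_run
            sign_c[doubled] = 1
        touched = np.zeros((m, 2), dtype=bool)  # one event per segment-allele per edge
        for _ in range(n_events):
            allele = int(rng.integers(2))
            gain = rng.random() < config.gain_prob
            s = 1 if gain else -1
            chrom = str(rng.integers(1, N_CHROMS + 1))
            on_chrom = np.flatnonzero(chrom_of == chrom)
            if on_chrom.size == 0:
                continue
            run_len = int(rng.geometric(1.0 / config.mean_run_length))
            start = int(rng.integers(on_chrom.size))
            targets = on_chrom[start:start + run_len]
            for t in targets:
                if touched[t, allele]:
                    continue
                new_c = c[t, j, allele] + s
                if new_c < 0 or new_c > config.c_max:
                    continue
                if c[t, j, allele] == 0:
                    continue  # LOH is irreversible
                extra_run = 1 if s != sign_c[t, allele] else 0
                if runs_c[t, allele] + extra_run > 2:
                    continue
                c[t, j, allele] = new_c
                runs_c[t, allele] += extra_run
                sign_c[t, allele] = s
                touched[t, allele] = True
        sign[clone] = sign_c
        runs[clone] = runs_c

    profile = CloneCNProfile(
        tuple(segments.segments), tuple(clones), c[..., 0], c[..., 1]
    )
    return tree, segments, profile


def simulate_proportions(
    tree: CloneTree, config: SimConfig, rng: np.random.Generator | None = None
) -> CloneProportions:
    """Clone fractions per sample.

    Each sample holds the union of the root paths of a few randomly drawn
    clones (an ancestor-closed set, as a physical sample contains a clone's
    ancestral lineage remnants), weighted by a floored Dirichlet draw and
    scaled by the sample purity.  Every clone is guaranteed to reach a
    minimal detectable fraction in at least one sample, mirroring the
    detection limit of SNV-based clone calling that the upstream clone
    proportions come from.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    clones = tree.tumour_clones
    n, k = len(clones), config.n_samples
    idx = {c: j for j, c in enumerate(clones)}
    present = np.zeros((n, k), dtype=bool)
    lo, hi = config.lineages_per_sample
    for r in range(k):
        n_lineages = int(rng.integers(lo, hi + 1))
        for _ in range(n_lineages):
            target = clones[int(rng.integers(n))]
            for node in tree.path_from_root(target)[1:]:
                present[idx[node], r] = True
    # guarantee every clone is sampled somewhere
    for j, clone in enumerate(clones):
        if not present[j].any():
            r = int(rng.integers(k))
            for node in tree.path_from_root(clone)[1:]:
                present[idx[node], r] = True

    purity = rng.uniform(*config.purity_range, size=k)
    w = np.zeros((n, k))
    for r in range(k):
        p = np.flatnonzero(present[:, r])
        raw = rng.dirichlet(np.full(p.size, config.dirichlet_alpha))
        floor = config.min_clone_fraction
        raw = floor + (1.0 - p.size * floor) * raw if p.size * floor < 1 else np.full(p.size, 1 / p.size)
        w[p, r] = raw
    # detection floor: each clone substantial in its best sample
    for j in range(n):
        r = int(np.argmax(w[j]))
        if w[j, r] < config.detection_fraction:
            w[j, r] = config.detection_fraction
    w /= w.sum(axis=0, keepdims=True)
    u = np.vstack([1.0 - purity, w * purity])
    return CloneProportions(tuple([NORMAL_CLONE] + list(clones)), tuple(f"sample{r+1}" for r in range(k)), u)


def draw_reads(
    truth: GroundTruth,
    rng: np.random.Generator,
    literal_formula: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """One draw of observed all-cell fractional copy numbers ``(x_hat, y_hat)``.

    ``t ~ Poisson(f/rho * gamma)`` and ``baf_hat ~ Binomial(gamma, beta)/gamma``
    are combined into ``x_hat = (t/gamma) * rho * (1 - baf_hat)`` and the
    B-allele analogue; these are unbiased for ``x_all`` and ``y_all``.
    ``literal_formula=True`` keeps the unnormalised rescaling ``t * rho``
    (in which the coverage factor is not divided out).
    """
    cfg = truth.config
    gamma = cfg.coverage
    f_all = truth.x_all + truth.y_all
    t = rng.poisson(np.maximum(f_all / truth.rho[None, :], 0.0) * gamma)
    successes = rng.binomial(int(gamma), truth.beta)
    baf_hat = successes / gamma
    scale = t * truth.rho[None, :] if literal_formula else (t / gamma) * truth.rho[None, :]
    return scale * (1.0 - baf_hat), scale * baf_hat


def simulate_reads(
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    exact: bool = False,
    literal_formula: bool = False,
) -> FractionalCN:
    """Observed fractional copy numbers from the Poisson/binomial read model.

    The all-cell draws from `draw_reads` are put on the tumour-mixture scale
    by subtracting the constant normal-cell contribution (one copy per allele
    times the normal fraction) and censoring at zero.  With ``exact=True``
    the estimates equal the true tumour-mixture values (bounds still carry
    the configured width): a noise-free experiment.
    """
    cfg = truth.config
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    half = cfg.bound_z * cfg.noise_sd

    if exact:
        est = np.stack([truth.fA, truth.fB], axis=2)
    else:
        x_hat, y_hat = draw_reads(truth, rng, literal_formula=literal_formula)
        u0 = 1.0 - truth.proportions.purity
        est = np.stack([x_hat - u0[None, :], y_hat - u0[None, :]], axis=2)
        est = np.maximum(est, 0.0)
    lo = np.maximum(est - half, 0.0)
    hi = est + half
    return FractionalCN(
        truth.profile.segments, truth.proportions.samples, est, lo, hi
    )


def simulate_tumour(config: SimConfig) -> tuple[GroundTruth, FractionalCN]:
    """Full pipeline: tree, profile, proportions, truth and observed data."""
    rng = np.random.default_rng(config.seed)
    tree, segments, profile = simulate_tree_and_profile(config, rng)
    proportions = simulate_proportions(tree, config, rng)
    from .core import mixture_fractional

    fA, fB = mixture_fractional(profile, proportions)
    u0 = 1.0 - proportions.purity
    x_all = fA + u0[None, :]
    y_all = fB + u0[None, :]
    f_all = x_all + y_all
    lengths = segments.lengths
    rho = (f_all * lengths[:, None]).sum(axis=0) / lengths.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(f_all > 0, y_all / np.where(f_all > 0, f_all, 1.0), 0.0)
    truth = GroundTruth(
        config=config,
        tree=tree,
        segments=segments,
        profile=profile,
        proportions=proportions,
        fA=fA,
        fB=fB,
        x_all=x_all,
        y_all=y_all,
        beta=beta,
        rho=rho,
    )
    observed = simulate_reads(truth, rng)
    return truth, observed


def export_truth(truth: GroundTruth, observed: FractionalCN, outdir: str | Path) -> dict[str, Path]:
    """Write tree, proportions, observed data, true profile and a manifest."""
    from .io import write_clone_profile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": outdir / "tree.tsv",
        "proportions": outdir / "proportions.tsv",
        "fractional": outdir / "fractional_cn.tsv",
        "true_profile": outdir / "true_clone_cn.tsv",
        "manifest": outdir / "manifest.yaml",
    }
    import pandas as pd

    pd.DataFrame(truth.tree.edges, columns=["parent", "child"]).to_csv(
        paths["tree"], sep="\t", index=False
    )
    truth.proportions.to_frame().to_csv(paths["proportions"], sep="\t", index=False)
    observed.to_frame(truth.segments).to_csv(paths["fractional"], sep="\t", index=False)
    write_clone_profile(truth.profile, truth.segments, paths["true_profile"])
    manifest = {"config": asdict(truth.config)}
    manifest["config"]["purity_range"] = list(truth.config.purity_range)
    manifest["config"]["lineages_per_sample"] = list(truth.config.lineages_per_sample)
    paths["manifest"].write_text(yaml.safe_dump(manifest, sort_keys=True))
    return paths
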