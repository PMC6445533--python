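"""Fragment-level simulation of the ChIP-seq protocol.

The experiment is simulated for a paired ChIP sample and a genomic-input
control, tracking exact fragment identity throughout:

1. Binding: at each of n loci the number of bound fragments across C cells
   is Binomial(C, p_b).
2. Extraction: bound fragments survive cross-linking/pull-down/size
   selection with per-locus probability p_e -> Binomial thinning.  The two
   samples' totals are then equalised by binomial down-sampling (factor D).
3. PCR: each extracted ("parent") fragment grows through n_cy cycles of a
   Galton-Watson branching process: every copy duplicates with probability
   p_a per cycle.  The copy-number distribution is computed exactly by
   recursive convolution and cached; closed-form moments are
   m = (1+p_a)^n_cy (the amplification ratio A) and
   v = (1-p_a) (1+p_a)^(n_cy-1) ((1+p_a)^n_cy - 1).
4. Sequencing: r = c*n reads are drawn from the pooled amplified fragments
   as a multivariate hypergeometric sample (sequential conditional scheme),
   then allocated within each locus to parent fragments the same way.  A
   parent contributes at most one unique read; its further sampled copies
   are PCR duplicates, so u_i + d_i = r_i exactly.

The per-locus unique-read ratio ChIP/input is the simulated peak intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import truncnorm

from .energy import (
    BindingConfig,
    TruncatedPowerLaw,
    accessibility_probability,
    cooperative_occupancy,
    CooperativeParams,
    indirect_occupancy,
    occupancy_probability,
    sample_energies,
)
from .rng import substream

__all__ = [
    "TruncatedNormalLaw",
    "amplification_probability",
    "simulate_binding",
    "extract_fragments",
    "equalize_samples",
    "pcr_distribution",
    "pcr_moments",
    "amplify",
    "sequence_reads",
    "allocate_to_parents",
    "deduplicate",
    "ExperimentResult",
    "run_experiment",
]

# Probability mass allowed to be truncated from the branching-process
# distribution tails; keeps moments accurate to ~1e-9 relative.
_TAIL_EPS = 1e-16
_PCR_CACHE: dict[tuple[float, int], np.ndarray] = {}


@dataclass(frozen=True)
class TruncatedNormalLaw:
    """Normal(mean, sd) truncated to [low, high]; the default heterogeneity
    model for extraction efficiency and amplification ratio."""

    mean: float
    sd: float
    low: float = 0.0
    high: float = 1.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, float(self.mean))
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)


def amplification_probability(A: float, n_cycles: int) -> float:
    """Invert A = (1 + p_a)^n_cy for the per-cycle success probability."""
    if A < 1 or A > 2**n_cycles:
        raise ValueError(f"amplification ratio {A} outside [1, 2^{n_cycles}]")
    return A ** (1.0 / n_cycles) - 1.0


def simulate_binding(p_bound, n_cells: int, rng: np.random.Generator) -> np.ndarray:
    """Bound-fragment counts: independent Binomial(n_cells, p_b) per locus."""
    p = np.asarray(p_bound, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("occupancy probabilities must lie in [0, 1]")
    return rng.binomial(n_cells, p)


def extract_fragments(f_bound, p_ext, rng: np.random.Generator) -> np.ndarray:
    """Binomial thinning of bound fragments by extraction efficiency.

    Composing several thinning stages is equivalent (in the first two
    moments, hence in distribution for binomials) to a single stage with
    the product probability, so p_ext aggregates the whole pre-PCR
    workflow.
    """
    f_bound = np.asarray(f_bound)
    p_ext = np.asarray(p_ext, dtype=float)
    if f_bound.shape != p_ext.shape:
        raise ValueError("f_bound and p_ext length mismatch")
    return rng.binomial(f_bound, p_ext)


def equalize_samples(
    chip: np.ndarray, inp: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Down-sample the richer sample so extracted totals match in expectation.

    D = sum(ChIP) / sum(input).  D < 1: input thinned by D; D > 1: ChIP
    thinned by 1/D; D = 1: unchanged.
    """
    tot_chip, tot_inp = int(np.sum(chip)), int(np.sum(inp))
    if tot_chip == 0 or tot_inp == 0:
        raise ValueError("degenerate run: a sample has zero extracted fragments")
    d = tot_chip / tot_inp
    if d < 1:
        inp = rng.binomial(inp, d)
    elif d > 1:
        chip = rng.binomial(chip, 1.0 / d)
    return chip, inp


def _binom_pmf_window(i: int, p: float, lo: int, hi: int) -> np.ndarray:
    """pmf of Binomial(i, p) on the integer window [lo, hi]."""
    j = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(i + 1)
        - gammaln(j + 1)
        - gammaln(i - j + 1)
        + j * math.log(p)
        + (i - j) * math.log1p(-p)
    )
    return np.exp(logpmf)


def pcr_distribution(p_a: float, n_cycles: int, *, grid: bool = False) -> np.ndarray:
    """Exact copy-number distribution of one fragment after n_cycles of PCR.

    Returns a vector ``probs`` where ``probs[k]`` is P(final copies = k+1);
    support is a subset of [1, 2^n_cycles].  Each cycle applies the
    branching recursion S_c = S_{c-1} + Binomial(S_{c-1}, p_a), convolving
    the current distribution with binomial offspring counts.  Tail mass
    below 1e-16 per entry is truncated (total < 1e-12, so moments are good
    to ~1e-9 relative).

    With ``grid=True`` p_a is first rounded to the 0.01 grid used by the
    precomputed distribution bank.
    """
    if not 0 < p_a < 1:
        raise ValueError(f"p_a must be in (0, 1), got {p_a}")
    if not 1 <= n_cycles <= 15:
        raise ValueError("n_cycles must be in [1, 15]")
    if grid:
        p_a = round(round(p_a / 0.01) * 0.01, 2)
        p_a = min(max(p_a, 0.01), 0.99)
    key = (round(p_a, 12), n_cycles)
    if key in _PCR_CACHE:
        return _PCR_CACHE[key]

    probs = np.array([1.0])  # offset: probs[k] = P(S = k + 1)
    for _ in range(n_cycles):
        cur_counts = np.arange(1, probs.size + 1)
        new = np.zeros(2 * probs.size)
        for idx, pi in enumerate(probs):
            if pi < _TAIL_EPS:
                continue
            i = int(cur_counts[idx])
            # offspring X ~ Binomial(i, p_a); keep a +-12 sigma window
            m = i * p_a
            s = math.sqrt(i * p_a * (1 - p_a))
            lo = max(0, int(m - 12 * s - 2))
            hi = min(i, int(m + 12 * s + 2))
            pmf = _binom_pmf_window(i, p_a, lo, hi)
            new[i + lo - 1 : i + hi] += pi * pmf
        probs = new
        # trim exact zeros at the tail to bound the support
        nz = np.nonzero(probs > 0)[0]
        probs = probs[: nz[-1] + 1]
    _PCR_CACHE[key] = probs
    return probs


def pcr_moments(p_a: float, n_cycles: int) -> tuple[float, float]:
    """Closed-form mean and variance of the PCR branching process."""
    if not 0 <= p_a <= 1:
        raise ValueError("p_a must be in [0, 1]")
    m = (1 + p_a) ** n_cycles
    v = (1 - p_a) * (1 + p_a) ** (n_cycles - 1) * ((1 + p_a) ** n_cycles - 1)
    return m, v


def amplify(
    f_extracted,
    p_amp,
    n_cycles: int,
    rng: np.random.Generator,
    *,
    grid: bool = True,
) -> list[np.ndarray]:
    """Amplify each locus's parent fragments through the branching process.

    Returns one array of per-parent copy numbers S_j >= 1 per locus.
    ``n_cycles = 0`` is the identity (all S_j = 1).
    """
    f_extracted = np.asarray(f_extracted)
    p_amp = np.broadcast_to(np.asarray(p_amp, dtype=float), f_extracted.shape)
    out: list[np.ndarray] = []
    for f, pa in zip(f_extracted, p_amp):
        f = int(f)
        if f == 0:
            out.append(np.empty(0, dtype=np.int64))
            continue
        if n_cycles == 0:
            out.append(np.ones(f, dtype=np.int64))
            continue
        probs = pcr_distribution(pa, n_cycles, grid=grid)
        support = np.arange(1, probs.size + 1)
        out.append(rng.choice(support, size=f, p=probs / probs.sum()))
    return out


def _hypergeom_draw(ngood: int, nbad: int, nsample: int, rng: np.random.Generator) -> int:
    """Hypergeometric draw valid for arbitrarily large populations.

    numpy's generator rejects populations above 1e9; amplified fragment
    pools routinely exceed that.  For large pools the draw falls back to
    inverse-CDF sampling on a +-12 sigma window of the exact log-pmf
    (mass outside the window is below ~1e-15).
    """
    if ngood < 1_000_000_000 and nbad < 1_000_000_000:
        return int(rng.hypergeometric(ngood, nbad, nsample))
    n_tot = ngood + nbad
    mean = nsample * ngood / n_tot
    var = nsample * (ngood / n_tot) * (nbad / n_tot) * (n_tot - nsample) / (n_tot - 1)
    half = 12.0 * math.sqrt(var) + 2
    lo = max(0, nsample - nbad, int(mean - half))
    hi = min(nsample, ngood, int(mean + half))
    k = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(ngood + 1) - gammaln(k + 1) - gammaln(ngood - k + 1)
        + gammaln(nbad + 1) - gammaln(nsample - k + 1) - gammaln(nbad - nsample + k + 1)
        - (gammaln(n_tot + 1) - gammaln(nsample + 1) - gammaln(n_tot - nsample + 1))
    )
    pmf = np.exp(logpmf - logpmf.max())
    cdf = np.cumsum(pmf)
    return int(k[np.searchsorted(cdf, rng.random() * cdf[-1])])


def sequence_reads(pool_sizes, total_reads: int, rng: np.random.Generator) -> np.ndarray:
    """Multivariate hypergeometric read allocation across locus pools.

    Sequential conditional scheme: reads for locus i are drawn from a
    univariate hypergeometric of pool i against the remaining pools, given
    the reads already assigned.  The joint law is exchangeable in locus
    order; sum(r_i) = total_reads exactly.
    """
    pools = np.asarray(pool_sizes, dtype=np.int64)
    total = int(pools.sum())
    if total_reads > total:
        raise ValueError(f"cannot sequence {total_reads} reads from {total} fragments")
    remaining_pool = total
    remaining_reads = int(total_reads)
    r = np.zeros(pools.size, dtype=np.int64)
    for i, a in enumerate(pools):
        a = int(a)
        remaining_pool -= a
        if remaining_reads == 0:
            break
        if remaining_pool == 0:
            r[i] = remaining_reads
            remaining_reads = 0
            break
        ri = _hypergeom_draw(a, remaining_pool, remaining_reads, rng)
        r[i] = ri
        remaining_reads -= ri
    return r


def _sample_distinct(n_pool: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """k distinct uniform integers from [0, n_pool) (= simple random sample)."""
    if k > n_pool:
        raise ValueError("cannot sample more items than the pool holds")
    if n_pool <= max(4 * k, 1024):
        return rng.choice(n_pool, size=k, replace=False)
    # rejection sampling: duplicates are rare when k << n_pool
    picked = np.unique(rng.integers(0, n_pool, size=k))
    while picked.size < k:
        extra = rng.integers(0, n_pool, size=k - picked.size)
        picked = np.unique(np.concatenate([picked, extra]))
    return picked


def allocate_to_parents(
    parent_sizes: np.ndarray, n_reads: int, rng: np.random.Generator
) -> np.ndarray:
    """Within-locus multivariate hypergeometric split of reads over parents.

    Every amplified fragment is equally likely to be sequenced, so sampling
    ``n_reads`` distinct fragments uniformly from the pooled copies and
    mapping them back to their parent is exactly the multivariate
    hypergeometric draw.  Returns reads per parent.
    """
    if n_reads == 0 or parent_sizes.size == 0:
        return np.zeros(parent_sizes.size, dtype=np.int64)
    bounds = np.cumsum(parent_sizes)
    frag_ids = _sample_distinct(int(bounds[-1]), int(n_reads), rng)
    parents = np.searchsorted(bounds, frag_ids, side="right")
    return np.bincount(parents, minlength=parent_sizes.size).astype(np.int64)


def deduplicate(parent_read_counts: np.ndarray) -> tuple[int, int]:
    """Unique/duplicate split at one locus.

    A parent fragment contributes exactly one unique read if sampled at
    all; its remaining sampled copies are PCR duplicates.
    """
    r = int(parent_read_counts.sum())
    u = int(np.count_nonzero(parent_read_counts))
    return u, r - u


# ---------------------------------------------------------------------------
# end-to-end orchestration


@dataclass
class ExperimentResult:
    """Output of one simulated ChIP + input experiment.

    ``table`` holds per-locus energies, occupancies, efficiencies, read
    counts and the unique-read ratio; the copy-number lists (reads per
    sampled parent fragment, per locus) feed FASTQ synthesis.
    """

    table: pd.DataFrame
    chip_copy_numbers: list[np.ndarray] = field(default_factory=list)
    input_copy_numbers: list[np.ndarray] = field(default_factory=list)
    n_undefined_ratio: int = 0

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _sequence_sample(
    f_extracted: np.ndarray,
    p_amp: np.ndarray,
    n_cycles: int,
    total_reads: int,
    rng: np.random.Generator,
    *,
    grid: bool = True,
):
    """Amplify, sequence, and de-duplicate one sample end to end."""
    parents = amplify(f_extracted, p_amp, n_cycles, rng, grid=grid)
    pools = np.array([int(s.sum()) for s in parents], dtype=np.int64)
    r = sequence_reads(pools, total_reads, rng)
    u = np.zeros_like(r)
    d = np.zeros_like(r)
    copy_numbers: list[np.ndarray] = []
    for i, s in enumerate(parents):
        per_parent = allocate_to_parents(s, int(r[i]), rng)
        u[i], d[i] = deduplicate(per_parent)
        copy_numbers.append(per_parent[per_parent > 0])
    return r, u, d, copy_numbers


def run_experiment(config, seed: int | None = None) -> ExperimentResult:
    """Simulate a full ChIP + input experiment from a SimulationConfig.

    Both samples share per-locus extraction and PCR efficiencies; each
    stage draws from its own child random stream of the root seed, so the
    whole run is bit-reproducible.
    """
    from .config import SimulationConfig  # local import to avoid cycle

    if not isinstance(config, SimulationConfig):
        config = SimulationConfig.model_validate(config)
    if seed is None:
        seed = config.seed

    cfg = BindingConfig(mu=config.mu, eps_u=config.eps_u)
    n = config.n_loci
    mode = config.binding_mode

    # --- energies and occupancies -----------------------------------------
    law_a = TruncatedPowerLaw(config.energy_alpha, config.energy_max)
    rng_e = substream(seed, "energies")
    if config.energies is not None:
        eps_a = np.asarray(config.energies, dtype=float)
        if eps_a.size != n:
            raise ValueError("supplied energies length != n_loci")
    else:
        eps_a = sample_energies(law_a, n, rng_e)

    eps_b = np.full(n, np.nan)
    labels = np.full(n, "direct", dtype=object)

    if mode == "direct":
        p_b = occupancy_probability(eps_a, cfg)
    elif mode == "indirect":
        k = int(round(config.indirect_fraction * n))
        law_b = TruncatedPowerLaw(config.b_energy_alpha, config.b_energy_max)
        eps_b = sample_energies(law_b, n, rng_e)
        p_b = occupancy_probability(eps_a, cfg)
        if k > 0:
            idx = rng_e.choice(n, size=k, replace=False)
            labels[idx] = "indirect"
            p_b = np.asarray(p_b)
            p_b[idx] = indirect_occupancy(eps_b[idx], config.mu_b, cfg)
    elif mode == "cooperative":
        k = int(round(config.cooperative_fraction * n))
        law_b = TruncatedPowerLaw(config.b_energy_alpha, config.b_energy_max)
        eps_b = sample_energies(law_b, n, rng_e)
        delta = np.zeros(n)
        if k > 0:
            idx = rng_e.choice(n, size=k, replace=False)
            labels[idx] = "cooperative"
            delta[idx] = config.delta
        p_b = cooperative_occupancy(
            CooperativeParams(eps_a, eps_b, config.mu, config.mu_b, 0.0), cfg
        )
        coop = labels == "cooperative"
        if np.any(coop):
            p_b = np.asarray(p_b)
            p_b[coop] = cooperative_occupancy(
                CooperativeParams(eps_a[coop], eps_b[coop], config.mu, config.mu_b, config.delta),
                cfg,
            )
    elif mode == "false_positive":
        # first n_loci are true positives; n_false_loci appended
        fp_law = config.false_positive_law()
        m = config.n_false_loci
        eps_fp = sample_energies(fp_law, m, rng_e)
        eps_a = np.concatenate([eps_a, eps_fp])
        eps_b = np.full(n + m, np.nan)
        labels = np.concatenate([np.full(n, "true_positive", dtype=object),
                                 np.full(m, "false_positive", dtype=object)])
        n = n + m
        p_b = occupancy_probability(eps_a, cfg)
    else:  # pragma: no cover - validated upstream
        raise ValueError(f"unknown binding mode {mode!r}")

    p_b = np.atleast_1d(np.asarray(p_b, dtype=float))

    # --- chromatin accessibility ------------------------------------------
    p_acc = np.ones(n)
    if config.accessibility_beta is not None:
        from .fixtures import make_density_track

        density = (
            np.asarray(config.accessibility_density, dtype=float)
            if config.accessibility_density is not None
            else make_density_track(n, substream(seed, "density"),
                                    scale=config.density_scale)
        )
        p_acc = np.asarray(accessibility_probability(density, config.accessibility_beta))
    p_occ = p_b * p_acc

    # --- input-sample occupancy -------------------------------------------
    p_bg = occupancy_probability(config.eps_bg, BindingConfig(mu=0.0, eps_u=config.eps_u))

    # --- binding + extraction ----------------------------------------------
    c_chip = config.n_cells
    c_input = int(round(config.input_cell_fraction * config.n_cells))
    fb_chip = simulate_binding(p_occ, c_chip, substream(seed, "binding", "chip"))
    fb_input = simulate_binding(np.full(n, p_bg), c_input, substream(seed, "binding", "input"))

    rng_ext = substream(seed, "extraction")
    p_ext = config.extraction_law().sample(n, rng_ext)
    fe_chip = extract_fragments(fb_chip, p_ext, substream(seed, "extract", "chip"))
    fe_input = extract_fragments(fb_input, p_ext, substream(seed, "extract", "input"))
    fe_chip, fe_input = equalize_samples(fe_chip, fe_input, substream(seed, "equalize"))

    # --- PCR efficiency ----------------------------------------------------
    amp_ratios = config.amplification_law().sample(n, substream(seed, "amp-ratio"))
    p_amp = np.array([amplification_probability(a, config.n_cycles) for a in amp_ratios])

    # --- amplification, sequencing, de-duplication -------------------------
    total_reads = config.depth * n
    rc, uc, dc, cn_chip = _sequence_sample(
        fe_chip, p_amp, config.n_cycles, total_reads,
        substream(seed, "sequence", "chip"), grid=config.pcr_grid,
    )
    ri, ui, di, cn_input = _sequence_sample(
        fe_input, p_amp, config.n_cycles, total_reads,
        substream(seed, "sequence", "input"), grid=config.pcr_grid,
    )

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ui > 0, uc / np.where(ui > 0, ui, 1), np.nan)

    table = pd.DataFrame(
        {
            "locus_id": np.arange(n),
            "chrom": "",
            "start": "",
            "end": "",
            "energy_A": eps_a,
            "energy_B": eps_b,
            "p_occupancy": p_occ,
            "p_ext": p_ext,
            "p_amp": p_amp,
            "chip_total": rc,
            "chip_unique": uc,
            "input_total": ri,
            "input_unique": ui,
            "ratio": ratio,
            "binding_mode": labels,
        }
    )
    return ExperimentResult(
        table=table,
        chip_copy_numbers=cn_chip,
        input_copy_numbers=cn_input,
        n_undefined_ratio=int(np.sum(ui == 0)),
    )
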