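"""Maximum-likelihood variant age under a linear birth-death process.

The mutant-allele class is modelled as a linear birth-death process
started from the single founding copy: each copy branches at rate
``lambda`` and dies at rate ``mu`` per generation, with growth
``d = lambda - mu``.  Two features of the data inform the age:

* the *allele frequency* — the implied present-day copy number
  ``N = n / f`` for ``n`` sampled carrier chromosomes and sampled
  proportion ``f`` — through the closed-form (geometric) copy-number law
  of the surviving process, and
* the *extent of intra-allelic variation* — operationalised as the
  partition of carrier chromosomes into flanking-haplotype classes,
  summarised by the count of chromosomes still carrying the intact
  ancestral haplotype.  The likelihood of that count is computed by
  Monte Carlo over genealogies from the growth-conditioned coalescent,
  either exactly per genealogy (class-size polynomial, known ancestral
  haplotype) or by re-simulating the entire data-summary pipeline on
  each genealogy (default when the ancestral haplotype is itself
  estimated from the carriers; see :func:`profile_likelihood`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    GeneticMap,
    Haplotype,
    HaplotypeSet,
    MarkerPanel,
    ValidationError,
)
from .trees import Genealogy

__all__ = [
    "BirthDeathParams",
    "AllelicClassSummary",
    "LikelihoodCurve",
    "bd_copy_number_pmf",
    "survival_probability",
    "simulate_bd_genealogy",
    "sample_reconstructed_coalescence_ages",
    "summarize_allelic_classes",
    "modal_carrier_haplotype",
    "class_exit_rate_from_map",
    "effective_class_exit_rate",
    "bdmc_likelihood",
    "profile_likelihood",
]


@dataclass(frozen=True)
class BirthDeathParams:
    """Per-lineage per-generation birth and death rates of the allele class."""

    birth_rate: float
    death_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.birth_rate <= 0:
            raise ValidationError("birth_rate must be positive")
        if self.death_rate < 0:
            raise ValidationError("death_rate must be non-negative")

    @property
    def growth(self) -> float:
        return self.birth_rate - self.death_rate

    @classmethod
    def from_growth(cls, d: float, death_rate: float = 1.0) -> "BirthDeathParams":
        """Discrete-generation scaling: lambda = death_rate + d (default mu = 1)."""
        return cls(birth_rate=death_rate + d, death_rate=death_rate)


def _alpha_beta(t: float, params: BirthDeathParams) -> tuple[float, float]:
    """Extinction weight alpha and geometric ratio beta of the linear
    birth-death transition law from one copy:  P(N=0) = alpha,
    P(N=k) = (1-alpha)(1-beta) beta^(k-1)."""
    lam, mu = params.birth_rate, params.death_rate
    if t == 0:
        return 0.0, 0.0
    if abs(lam - mu) < 1e-12:
        b = lam * t / (1.0 + lam * t)
        return b, b
    E = math.exp((lam - mu) * t)
    denom = lam * E - mu
    alpha = mu * (E - 1.0) / denom
    beta = lam * (E - 1.0) / denom
    return alpha, beta


def survival_probability(t: float, params: BirthDeathParams) -> float:
    alpha, _ = _alpha_beta(t, params)
    return 1.0 - alpha


def bd_copy_number_pmf(t: float, params: BirthDeathParams, n_max: int) -> np.ndarray:
    """P(copy number = k | survival to age t), for k = 1..n_max.

    Conditioned on non-extinction the copy number is geometric with
    ratio ``beta``; the returned vector carries mass ``1 - beta**n_max``
    (the remainder is the documented tail beyond ``n_max``).
    """
    if t < 0:
        raise ValidationError("t must be non-negative")
    if n_max < 1:
        raise ValidationError("n_max must be at least 1")
    _, beta = _alpha_beta(t, params)
    k = np.arange(1, n_max + 1)
    if beta == 0.0:
        pmf = np.zeros(n_max)
        pmf[0] = 1.0
        return pmf
    return (1.0 - beta) * beta ** (k - 1)


def _log_copy_number_pmf(t: float, params: BirthDeathParams, n_copies: int) -> float:
    _, beta = _alpha_beta(t, params)
    if beta == 0.0:
        return 0.0 if n_copies == 1 else -math.inf
    return math.log(1.0 - beta) + (n_copies - 1) * math.log(beta)


def expected_copies_given_survival(t: float, params: BirthDeathParams) -> float:
    """E[N | survival] = exp(d t) / P(survival) from the closed form."""
    surv = survival_probability(t, params)
    return math.exp(params.growth * t) / surv


# ---------------------------------------------------------------------------
# forward simulation and genealogy extraction


def _extract_genealogy(
    parent_rec: np.ndarray,
    tbirth: np.ndarray,
    sample_ids: Sequence[int],
    t: float,
) -> Genealogy:
    """Reduced genealogy of ``sample_ids`` from a forward birth-death record.

    Each recorded individual is a spine running from its birth to the
    present; a birth attaches a child spine at the birth time.  The
    reduced tree keeps only spines ancestral to the sample and folds each
    spine's sample-bearing attachments into binary coalescences at the
    attachment ages (age = t - forward time).
    """
    n = len(sample_ids)
    sample_set = set(int(s) for s in sample_ids)
    relevant = set()
    for s in sample_ids:
        u = int(s)
        while u >= 0 and u not in relevant:
            relevant.add(u)
            u = int(parent_rec[u])
    rel_children: dict[int, list[int]] = {u: [] for u in relevant}
    for u in relevant:
        p = int(parent_rec[u])
        if p >= 0:
            rel_children[p].append(u)
    for u in relevant:
        rel_children[u].sort(key=lambda c: tbirth[c])

    leaf_index = {int(s): i for i, s in enumerate(sample_ids)}
    size = 2 * n - 1
    parent = np.full(size, -1, dtype=np.int64)
    node_time = np.zeros(size)
    internal_ages: list[float] = []
    internal_pairs: list[tuple[int, int]] = []

    # iterative post-order over the relevant forest rooted at individual 0
    result: dict[int, int | None] = {}
    order: list[int] = []
    stack = [0]
    while stack:
        u = stack.pop()
        order.append(u)
        stack.extend(rel_children[u])
    tmp_nodes: list[tuple[float, int, int]] = []  # (age, child_a, child_b) temp ids

    def new_internal(age: float, a: int, b: int) -> int:
        tmp_nodes.append((age, a, b))
        return n + len(tmp_nodes) - 1

    for u in reversed(order):
        cur: int | None = leaf_index.get(u)
        for c in sorted(rel_children[u], key=lambda c: -tbirth[c]):
            sub = result[c]
            if sub is None:
                continue
            if cur is None:
                cur = sub
            else:
                cur = new_internal(t - tbirth[c], cur, sub)
        result[u] = cur
    root_tmp = result[0]
    if n == 1:
        return Genealogy(1, np.array([-1]), np.array([0.0]), float(t))
    # renumber internals in ascending age
    order_idx = sorted(range(len(tmp_nodes)), key=lambda i: tmp_nodes[i][0])
    remap = {n + i: n + rank for rank, i in enumerate(order_idx)}
    for rank, i in enumerate(order_idx):
        age, a, b = tmp_nodes[i]
        nid = n + rank
        node_time[nid] = age
        for child in (a, b):
            cid = child if child < n else remap[child]
            parent[cid] = nid
    return Genealogy(n, parent, node_time, float(t))


def simulate_bd_genealogy(
    n_sampled: int,
    t: float,
    params: BirthDeathParams,
    seed: int = 0,
    max_retries: int = 1000,
) -> Genealogy:
    """Genealogy of ``n_sampled`` uniformly sampled survivors of a forward
    birth-death realisation from one founder copy at age ``t``,
    conditioned (by rejection) on at least ``n_sampled`` survivors.
    """
    from ._kernels import bd_forward

    if n_sampled < 1:
        raise ValidationError("n_sampled must be at least 1")
    if t < 0:
        raise ValidationError("t must be non-negative")
    rng = np.random.default_rng(seed)
    cap = int(1000 + 40 * math.exp(params.growth * t))
    for attempt in range(max_retries):
        kseed = int(rng.integers(2**31 - 1))
        status, count, parent_rec, tbirth, alive, n_alive = bd_forward(
            float(t), params.birth_rate, params.death_rate, kseed, cap
        )
        if status == 1:
            cap *= 2
            continue
        if n_alive < n_sampled:
            continue
        survivors = alive[:n_alive]
        sample = rng.choice(survivors, size=n_sampled, replace=False)
        return _extract_genealogy(parent_rec, tbirth, list(map(int, sample)), float(t))
    raise ValidationError(
        f"could not obtain {n_sampled} survivors at age {t} in {max_retries} "
        "attempts; check the birth-death parameters"
    )


def bd_population_size(t: float, params: BirthDeathParams, seed: int = 0,
                       min_survivors: int = 1, max_retries: int = 10_000) -> int:
    """One forward draw of the surviving copy number at age ``t``,
    conditioned on at least ``min_survivors`` survivors."""
    from ._kernels import bd_forward

    rng = np.random.default_rng(seed)
    cap = int(1000 + 40 * math.exp(params.growth * t))
    for _ in range(max_retries):
        kseed = int(rng.integers(2**31 - 1))
        status, _count, _p, _tb, _alive, n_alive = bd_forward(
            float(t), params.birth_rate, params.death_rate, kseed, cap
        )
        if status == 1:
            cap *= 2
            continue
        if n_alive >= min_survivors:
            return int(n_alive)
    raise ValidationError("conditioning failed; check the parameters")


# ---------------------------------------------------------------------------
# reconstructed-process genealogies (analytic coalescence ages)


def sample_reconstructed_coalescence_ages(
    n: int, t: float, params: BirthDeathParams, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """The n-1 coalescence ages of a rho-sampled reconstructed birth-death
    tree of origin age ``t``: independent draws from the closed-form
    age CDF, returned sorted ascending."""
    u = rng.random(n - 1)
    return np.sort(_invert_ages(u, t, params, rho))


def _invert_ages(u: np.ndarray, t: float, params: BirthDeathParams, rho: float) -> np.ndarray:
    lam, mu = params.birth_rate, params.death_rate
    d = lam - mu
    A = rho * lam
    B = mu - lam * (1.0 - rho)
    if abs(d) < 1e-12:
        # critical limit: q(s) = s / (1 + A s)
        qt = t / (1.0 + A * t)
        y = u * qt
        return y / (1.0 - A * y)
    Et = math.exp(-d * t)
    qt = (1.0 - Et) / (A - B * Et)
    y = u * qt
    E = (1.0 - y * A) / (1.0 - y * B)
    return np.clip(-np.log(np.maximum(E, 1e-300)) / d, 0.0, t)


# ---------------------------------------------------------------------------
# the data summary and the likelihood


@dataclass(frozen=True)
class AllelicClassSummary:
    """Partition of carrier chromosomes into flanking-haplotype classes."""

    n_sampled: int
    sampled_proportion: float
    class_counts: tuple[int, ...]  # sorted descending; sums to n_sampled
    intact_count: Optional[int] = None  # chromosomes matching the ancestral
    # haplotype everywhere (may be 0, which class_counts cannot express)

    def __post_init__(self) -> None:
        if self.n_sampled < 1:
            raise ValidationError("n_sampled must be at least 1")
        if not (0 < self.sampled_proportion <= 1):
            raise ValidationError("sampled_proportion must be in (0, 1]")
        if sum(self.class_counts) != self.n_sampled:
            raise ValidationError("class counts must sum to n_sampled")

    @property
    def ancestral_class_size(self) -> int:
        if self.intact_count is not None:
            return self.intact_count
        return max(self.class_counts)

    @property
    def implied_copy_number(self) -> int:
        return max(self.n_sampled, round(self.n_sampled / self.sampled_proportion))


def modal_carrier_haplotype(
    carriers: HaplotypeSet | Sequence[Haplotype],
) -> tuple[str, ...]:
    """Per-marker modal allele among carrier chromosomes — the working
    estimate of the ancestral haplotype (ties broken by symbol order)."""
    haps = carriers.carriers if isinstance(carriers, HaplotypeSet) else list(carriers)
    if not haps:
        raise ValidationError("no carrier chromosomes")
    m = len(haps[0].alleles)
    out = []
    for i in range(m):
        counts: dict[str, int] = {}
        for h in haps:
            a = h.alleles[i]
            if a != MISSING:
                counts[a] = counts.get(a, 0) + 1
        out.append(
            sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0] if counts else MISSING
        )
    return tuple(out)


def summarize_allelic_classes(
    carriers: HaplotypeSet | Sequence[Haplotype],
    sampled_proportion: float,
    ancestral: Optional[Sequence[str]] = None,
    statistic: str = "intact",
) -> AllelicClassSummary:
    """Summarise intra-allelic variation among carrier chromosomes.

    ``statistic="intact"`` (default) counts chromosomes matching the
    ancestral haplotype at every non-missing marker (``ancestral``
    defaults to the per-marker modal carrier allele), the remainder
    forming singleton classes; this is the statistic the likelihood
    models, since a recombinant clade shares its post-crossover
    background and would otherwise masquerade as a large "conserved"
    class.  ``statistic="classes"`` partitions carriers by their full
    marker haplotype (missing alleles are wildcards that join the first
    compatible class, checked largest-first) and summarises by the
    largest class.
    """
    haps = carriers.carriers if isinstance(carriers, HaplotypeSet) else list(carriers)
    if not haps:
        raise ValidationError("no carrier chromosomes to summarise")
    rows = [h.alleles for h in haps]
    n = len(rows)
    if statistic == "intact":
        if ancestral is None:
            ancestral = modal_carrier_haplotype(haps)
        k = sum(
            1
            for r in rows
            if all(a == MISSING or a == b for a, b in zip(r, ancestral))
        )
        counts = ([k] if k else []) + [1] * (n - k)
        return AllelicClassSummary(
            n, sampled_proportion, tuple(sorted(counts, reverse=True)), intact_count=k
        )
    if statistic != "classes":
        raise ValidationError(f"unknown statistic {statistic!r}")
    complete = [r for r in rows if MISSING not in r]
    classes: list[tuple[tuple[str, ...], int]] = []
    counts_map: dict[tuple[str, ...], int] = {}
    for r in complete:
        counts_map[r] = counts_map.get(r, 0) + 1
    wild = [r for r in rows if MISSING in r]
    for r in wild:
        for rep in sorted(counts_map, key=counts_map.get, reverse=True):
            if all(a == MISSING or a == b for a, b in zip(r, rep)):
                counts_map[rep] += 1
                break
        else:
            counts_map[r] = counts_map.get(r, 0) + 1
    counts = tuple(sorted(counts_map.values(), reverse=True))
    return AllelicClassSummary(n, sampled_proportion, counts)


def class_exit_rate_from_map(
    panel: MarkerPanel, gmap: GeneticMap, extrapolate: bool = True
) -> float:
    """Per-generation rate at which recombination strikes the marker window.

    Sum of the genetic lengths (in Morgans) from the variant to the
    outermost marker on each side: a crossover anywhere in the window
    moves a chromosome out of the ancestral haplotype class.
    """
    v = panel.focal_variant.position_bp
    left = gmap.distance_cM(panel.markers[0].position_bp, v, extrapolate)
    right = gmap.distance_cM(panel.markers[-1].position_bp, v, extrapolate)
    return (left + right) / 100.0


def effective_class_exit_rate(
    panel: MarkerPanel,
    gmap: GeneticMap,
    freqs: Sequence[dict],
    ancestral: Sequence[str],
    extrapolate: bool = True,
) -> float:
    """Per-generation rate of *visible* exits from the ancestral class.

    A crossover between markers ``j`` and ``j+1`` replaces every marker
    beyond ``j`` with population material, but the chromosome only
    leaves the observable intact class if at least one replaced allele
    differs from the ancestral one; a crossover in the outermost
    interval (replacing a single marker) is invisible with the
    population frequency of that marker's ancestral allele.  Each
    inter-marker interval therefore contributes its genetic length times
    ``1 - prod(p_i(a_i))`` over the replaced markers.  Monomorphic
    markers are transparent automatically (``p = 1``).
    """
    v = panel.focal_variant.position_bp
    rate = 0.0
    for side in ("proximal", "distal"):
        idx = [i for i, m in enumerate(panel.markers) if panel.side(m) == side]
        if side == "proximal":
            idx = idx[::-1]  # walk outwards from the variant
        if not idx:
            continue
        dists = [gmap.distance_cM(panel.markers[i].position_bp, v, extrapolate) / 100.0
                 for i in idx]
        prev = 0.0
        for k, (i, g) in enumerate(zip(idx, dists)):
            # crossover in (prev, g) replaces markers idx[k:]
            p_coinc = 1.0
            for ii in idx[k:]:
                a = ancestral[ii]
                p_coinc *= freqs[ii].get(a, 0.0) if a != MISSING else 1.0
            rate += (g - prev) * (1.0 - p_coinc)
            prev = g
    return rate


def bdmc_likelihood(
    t: float,
    summary: AllelicClassSummary,
    params: BirthDeathParams,
    class_exit_rate: float = 0.0,
    n_reps: int = 10_000,
    seed: int = 0,
    panel: Optional[MarkerPanel] = None,
    gmap: Optional[GeneticMap] = None,
    freqs: Optional[Sequence[dict]] = None,
    method: str = "exact_ancestral",
) -> tuple[float, float]:
    """Monte-Carlo log-likelihood of the age ``t`` with its standard error.

    Averages P(intact-class count | genealogy) over growth-conditioned
    coalescent genealogies and multiplies by the copy-number term
    P(N = n/f | t, survival).  The standard error is delta-method on the
    log of the Monte-Carlo mean.  See :func:`profile_likelihood` for the
    two evaluation methods.
    """
    if n_reps < 100:
        raise ValidationError("n_reps must be at least 100")
    curve = profile_likelihood(
        summary,
        params,
        [float(t)],
        n_reps=n_reps,
        seed=seed,
        class_exit_rate=class_exit_rate,
        panel=panel,
        gmap=gmap,
        freqs=freqs,
        method=method,
    )
    return float(curve.loglik[0]), float(curve.mc_se[0])


@dataclass(frozen=True)
class LikelihoodCurve:
    """Profile of the Monte-Carlo log-likelihood over candidate ages."""

    grid: np.ndarray
    loglik: np.ndarray
    mc_se: np.ndarray
    ml_age: float
    ci95: tuple[float, float]
    n_reps: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.grid, "loglik": self.loglik, "mc_se": self.mc_se})

    def summary_dict(self) -> dict:
        return {
            "ml_age_generations": self.ml_age,
            "ci95_generations": list(self.ci95),
            "n_reps": self.n_reps,
            "seed": self.seed,
        }


def profile_likelihood(
    summary: AllelicClassSummary,
    params: BirthDeathParams,
    grid: Sequence[float],
    n_reps: int = 10_000,
    seed: int = 0,
    class_exit_rate: float = 0.0,
    panel: Optional[MarkerPanel] = None,
    gmap: Optional[GeneticMap] = None,
    freqs: Optional[Sequence[dict]] = None,
    method: str = "exact_ancestral",
    f_uncertainty_log_sd: float = 0.0,
) -> LikelihoodCurve:
    """Likelihood over an age grid with common random numbers across ages.

    ``method="exact_ancestral"`` computes P(intact count | genealogy)
    exactly on each Monte-Carlo genealogy via the class-size polynomial,
    treating the summary's intact count as measured against the true
    ancestral haplotype with exits at ``class_exit_rate``.
    ``method="pipeline"`` (requires ``panel``, ``gmap`` and ``freqs``)
    instead simulates marker data on each genealogy and re-applies the
    same modal-ancestral intact-count pipeline that produced the data
    summary, so the plug-in ancestral-haplotype selection bias is part
    of the model; use it when the ancestral haplotype was estimated from
    the carriers themselves.  Both share uniform draws across grid ages
    (common random numbers), and both multiply the copy-number term
    P(N = n/f | t).  The 95% interval is read from the normalised
    likelihood mass over the grid (flat prior); the maximum is the grid
    argmax.

    ``f_uncertainty_log_sd`` (pipeline method only) treats the sampled
    proportion as a noisy estimate rather than a known constant: the
    present-day copy number C is integrated out over the birth-death
    law P(C | t) weighted by a lognormal measurement model for the
    implied n/f (log-scale sd as given), via quadrature on a log-spaced
    C grid.  Use it when f is itself a rough projection; leave 0 when
    the sampled proportion is known exactly.
    """
    grid_arr = np.asarray(sorted(float(g) for g in grid))
    if len(grid_arr) == 0:
        raise ValidationError("grid must be non-empty")
    if np.any(grid_arr <= 0):
        raise ValidationError("grid ages must be positive")
    from ._kernels import bd_class_profile, bd_pipeline_profile

    n = summary.n_sampled
    k_obs = summary.ancestral_class_size
    rng = np.random.default_rng(seed)
    if method == "pipeline":
        if panel is None or gmap is None or freqs is None:
            raise ValidationError('method="pipeline" needs panel, gmap and freqs')
        if n < 2:
            raise ValidationError('method="pipeline" needs at least 2 chromosomes')
        v = panel.focal_variant.position_bp
        dist = np.array(
            [gmap.distance_cM(m.position_bp, v, extrapolate=True) / 100.0
             for m in panel.markers]
        )
        is_left = np.array([m.position_bp < v for m in panel.markers])
        alphabets = [sorted(a for a, f in table.items() if f > 0) or [MISSING]
                     for table in freqs]
        Kmax = max(len(a) for a in alphabets)
        freq_arr = np.zeros((len(panel), Kmax))
        n_all = np.zeros(len(panel), dtype=np.int64)
        for i, alpha in enumerate(alphabets):
            n_all[i] = len(alpha)
            for kk, a in enumerate(alpha):
                freq_arr[i, kk] = freqs[i].get(a, 1.0)
            freq_arr[i, : n_all[i]] /= freq_arr[i, : n_all[i]].sum()
        base_seed = int(rng.integers(2**31 - 1))
        C0 = float(summary.implied_copy_number)

        def _sim(C_val):
            return bd_pipeline_profile(
                grid_arr,
                int(n),
                int(n_reps),
                base_seed,
                params.growth,
                float(C_val),
                dist,
                is_left,
                freq_arr,
                n_all,
                int(k_obs),
            )

        if f_uncertainty_log_sd <= 0.0:
            mean = _sim(C0)
            var = mean * (1.0 - mean)
            n_copies = summary.implied_copy_number
            ll_extra = np.array(
                [_log_copy_number_pmf(t, params, n_copies) for t in grid_arr]
            )
        else:
            # integrate the copy number out: C-grid quadrature combining the
            # birth-death law P(C | t) with a lognormal measurement model
            # for the implied n/f (the same uniforms serve every C point)
            sd = f_uncertainty_log_sd
            logC0 = math.log(max(C0, n + 1))
            log_grid = np.linspace(logC0 - 2.5 * sd, logC0 + 2.5 * sd, 7)
            log_grid = log_grid[np.exp(log_grid) >= n]
            dlog = log_grid[1] - log_grid[0] if len(log_grid) > 1 else 1.0
            comps = []
            for lC in log_grid:
                Cj = float(np.exp(lC))
                pj = _sim(Cj)
                meas = -0.5 * ((lC - logC0) / sd) ** 2
                bd_term = np.array(
                    [_log_copy_number_pmf(t, params, int(round(Cj))) for t in grid_arr]
                )
                # density over log C: P(C|t) * C * dlogC
                with np.errstate(divide="ignore"):
                    comps.append(np.log(np.maximum(pj, 1e-300)) + bd_term + meas + lC
                                 + math.log(dlog))
                comps[-1][pj <= 0.0] = -np.inf
            stack = np.vstack(comps)
            mx = np.max(stack, axis=0)
            with np.errstate(invalid="ignore"):
                mean = np.where(
                    np.isfinite(mx), np.exp(mx) * np.exp(stack - mx).sum(axis=0), 0.0
                )
            var = np.maximum(mean, 1e-300) * 1.0  # rough binomial-scale spread
            ll_extra = np.zeros_like(mean)  # copy-number term already inside
    elif method != "exact_ancestral":
        raise ValidationError(f"unknown method {method!r}")
    elif n > 1:
        U = rng.random((n_reps, n - 1))
        J = rng.random((n_reps, n - 1, 2))
        mean, var = bd_class_profile(
            grid_arr,
            U,
            J,
            int(k_obs),
            params.growth,
            float(summary.implied_copy_number),
            float(class_exit_rate),
        )
        ll_extra = np.array(
            [_log_copy_number_pmf(t, params, summary.implied_copy_number)
             for t in grid_arr]
        )
    else:
        # single chromosome: class intact iff no exit on the stem
        s = np.exp(-class_exit_rate * grid_arr)
        mean = s if k_obs == 1 else 1.0 - s
        var = np.zeros_like(mean)
        ll_extra = np.array(
            [_log_copy_number_pmf(t, params, summary.implied_copy_number)
             for t in grid_arr]
        )
    if np.any(mean <= 0.0):
        warnings.warn(
            "the observed class configuration had zero probability in every "
            "replicate at some grid ages; those ages get -inf log-likelihood"
        )
    with np.errstate(divide="ignore"):
        ll_mc = np.log(mean)
    se = np.zeros_like(mean)
    pos = mean > 0
    se[pos] = np.sqrt(np.maximum(var[pos], 0.0) / n_reps) / mean[pos]
    ll = ll_mc + ll_extra

    finite = np.isfinite(ll)
    if not np.any(finite):
        raise ValidationError("likelihood is zero on the whole grid; check the inputs")
    # the argmax is taken on a locally averaged curve (+-2 grid points on
    # the likelihood scale) so that residual Monte-Carlo jitter does not
    # drag the point estimate along a flat shoulder; the reported curve
    # itself is unsmoothed
    lik = np.where(finite, np.exp(ll - np.max(ll[finite])), 0.0)
    kernel = np.ones(min(5, len(lik)))
    smooth = np.convolve(lik, kernel, mode="same") / np.convolve(
        np.ones_like(lik), kernel, mode="same"
    )
    i_ml = int(np.argmax(smooth))
    ml_age = float(grid_arr[i_ml])
    ci = _mass_interval(grid_arr, ll)
    _warn_if_multimodal(grid_arr, ll, se)
    return LikelihoodCurve(
        grid=grid_arr,
        loglik=ll,
        mc_se=se,
        ml_age=ml_age,
        ci95=ci,
        n_reps=n_reps,
        seed=seed,
    )


def _mass_interval(grid: np.ndarray, ll: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Central interval of the normalised likelihood over the grid."""
    if len(grid) == 1:
        return (float(grid[0]), float(grid[0]))
    w = np.exp(ll - np.nanmax(ll[np.isfinite(ll)]))
    w[~np.isfinite(w)] = 0.0
    # trapezoid cumulative mass over the (possibly uneven) grid
    seg = 0.5 * (w[1:] + w[:-1]) * np.diff(grid)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0:
        return (float(grid[0]), float(grid[-1]))
    cum /= total
    lo_q, hi_q = (1 - mass) / 2, 1 - (1 - mass) / 2
    lo = float(np.interp(lo_q, cum, grid))
    hi = float(np.interp(hi_q, cum, grid))
    return (lo, hi)


def _warn_if_multimodal(grid: np.ndarray, ll: np.ndarray, se: np.ndarray) -> None:
    finite = np.isfinite(ll)
    llf = ll[finite]
    sef = se[finite]
    if len(llf) < 5:
        return
    peaks = 0
    for i in range(1, len(llf) - 1):
        tol = 3.0 * max(sef[i - 1], sef[i], sef[i + 1])
        if llf[i] > llf[i - 1] + tol and llf[i] > llf[i + 1] + tol:
            peaks += 1
    if peaks > 1:
        warnings.warn(
            f"likelihood curve shows {peaks} local maxima beyond Monte-Carlo "
            "noise; interpret the interval with care"
        )
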