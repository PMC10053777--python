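"""Synthetic inputs with the statistical structure the analysis assumes.

The generators emulate the study design: a shared vehicle control plus two
environmental-mixture exposures whose per-gene log2 effects are proportional
(the weaker mixture's effect is a scalar multiple ``beta`` of the stronger
one's, plus gene-level noise), negative-binomial counts with a common
dispersion, gene-set collections with planted coherently-regulated terms,
binomial developmental-screen data at n=40 fish per dose, and two PAH
concentration profiles that differ by a scale factor while sharing
source-diagnostic ratios.

Every generator draws from an independent stream spawned from one master
seed, so modules can be tested in isolation yet a whole pipeline run is
reproducible from a single integer.

Defaults are the study conditions: effect ratio ``beta=0.59``, exposure
dilution series (1.0, 0.2, 0.04, 0.008)% with 40 fish per dose, term sizes
within the 15-400 gene window, and a two-site PAH panel at a 1.63x
concentration ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import CountMatrix

# Stream ids for SeedSequence fan-out; one per generator.
_STREAM_COUNTS = 0
_STREAM_GENESETS = 1
_STREAM_TOX = 2
_STREAM_CHEM = 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for one stream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass
class SynthTruth:
    """Ground truth behind one synthetic dataset, for parameter-recovery tests.

    Attributes
    ----------
    theta : per-gene latent log2 effect of the stronger mixture (0 for null genes).
    beta : scalar effect ratio of the weaker mixture (its effect is
        ``beta * theta + eps`` for differentially expressed genes).
    eps_sd : s.d. of the gene-level noise ``eps`` on the weaker mixture's effect.
    alpha : NB dispersion in the ``var = mu + alpha * mu**2`` convention.
    base_mean : per-gene baseline mean at size factor 1.
    lib_sizes : per-sample size factors (filled by :func:`gen_counts`).
    active_terms : term ids planted as coherently regulated (filled by
        :func:`gen_genesets`).
    seed : master seed that all generator streams fan out from.
    """

    theta: np.ndarray
    beta: float = 0.59
    eps_sd: float = 0.3
    alpha: float = 0.05
    base_mean: np.ndarray | None = None
    lib_sizes: np.ndarray | None = None
    active_terms: set[str] = field(default_factory=set)
    eps: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.alpha < 0:
            raise ValueError(f"NB dispersion alpha must be >= 0, got {self.alpha}")
        if self.eps_sd < 0:
            raise ValueError("eps_sd must be >= 0")
        if self.lib_sizes is not None and np.any(np.asarray(self.lib_sizes) <= 0):
            raise ValueError("library size factors must be > 0")

    @property
    def n_genes(self) -> int:
        return self.theta.size

    @property
    def de_genes(self) -> np.ndarray:
        """Boolean mask of genes with a planted effect."""
        return self.theta != 0

    def gene_ids(self) -> list[str]:
        return [f"gene{i:05d}" for i in range(self.n_genes)]

    def to_frame(self) -> pd.DataFrame:
        """Truth sidecar as a tidy table (one row per gene)."""
        df = pd.DataFrame({"gene_id": self.gene_ids(), "theta": self.theta})
        if self.eps is not None:
            df["eps"] = self.eps
        if self.base_mean is not None:
            df["base_mean"] = self.base_mean
        return df


def make_truth(
    n_genes: int,
    de_fraction: float = 0.1,
    lfc_range: tuple[float, float] = (0.5, 3.0),
    beta: float = 0.59,
    eps_sd: float = 0.3,
    alpha: float = 0.05,
    seed: int = 0,
) -> SynthTruth:
    """Draw a per-gene effect vector: ``de_fraction`` of genes get
    ``theta ~ +/- Uniform(lfc_range)`` in log2 units, the rest are null."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must be in [0, 1]")
    rng = _rng(seed, _STREAM_COUNTS)
    theta = np.zeros(n_genes)
    n_de = int(round(de_fraction * n_genes))
    idx = rng.choice(n_genes, size=n_de, replace=False)
    mag = rng.uniform(lfc_range[0], lfc_range[1], size=n_de)
    sign = rng.choice([-1.0, 1.0], size=n_de)
    theta[idx] = sign * mag
    return SynthTruth(theta=theta, beta=beta, eps_sd=eps_sd, alpha=alpha, seed=seed)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean mu, var mu + alpha mu^2); Poisson when alpha == 0."""
    if alpha == 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    # gamma-Poisson mixture keeps shapes broadcastable
    lam = rng.gamma(shape=r, scale=mu / r)
    return rng.poisson(lam)


def gen_counts(
    n_genes: int,
    samples_per_group: int,
    truth: SynthTruth | None = None,
    *,
    groups: tuple[str, ...] = ("control", "mixtureA", "mixtureB"),
    extra_group_scales: dict[str, float] | None = None,
    mean_log_mu: float = np.log(100.0),
    mean_log_sd: float = 1.0,
    lib_size_sd: float = 0.1,
    seed: int = 0,
) -> tuple[CountMatrix, SynthTruth]:
    """Simulate an NB count matrix for a control and several treatments.

    Per-gene group means are ``mu_g * s_j * 2**L`` where ``L`` is 0 for the
    control, ``theta_g`` for mixtureA, and ``beta*theta_g + eps_g`` for
    mixtureB (``eps`` only on genes with a planted effect, so null genes are
    exactly null in every group). Size factors are lognormal(0, ``lib_size_sd``).
    ``extra_group_scales`` adds further treatment groups whose log2 effect is
    the given scalar multiple of ``theta`` (no extra noise) — stand-ins for
    single-chemical exposures.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if samples_per_group < 2:
        raise ValueError("samples_per_group must be >= 2 (replication is required downstream)")
    if truth is None:
        truth = make_truth(n_genes, seed=seed)
    if truth.n_genes != n_genes:
        raise ValueError("truth.theta length does not match n_genes")

    rng = _rng(truth.seed, _STREAM_COUNTS).spawn(1)[0]
    group_names = list(groups)
    if "control" not in group_names:
        raise ValueError("groups must include 'control'")
    for g, sc in (extra_group_scales or {}).items():
        group_names.append(g)

    base_mean = rng.lognormal(mean=mean_log_mu, sigma=mean_log_sd, size=n_genes)
    n_samples = samples_per_group * len(group_names)
    lib = rng.lognormal(mean=0.0, sigma=lib_size_sd, size=n_samples)
    if np.any(lib <= 0):
        raise ValueError("library size factors must be > 0")

    eps = np.zeros(n_genes)
    de = truth.de_genes
    if truth.eps_sd > 0:
        eps[de] = rng.normal(0.0, truth.eps_sd, size=int(de.sum()))

    effects = {"control": np.zeros(n_genes)}
    for g in group_names:
        if g == "control":
            continue
        if g == "mixtureA":
            effects[g] = truth.theta
        elif g == "mixtureB":
            effects[g] = truth.beta * truth.theta + eps
        else:
            effects[g] = (extra_group_scales or {})[g] * truth.theta

    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    sample_ids, sample_groups = [], []
    j = 0
    for g in group_names:
        mu_group = base_mean * np.exp2(effects[g])
        for r in range(samples_per_group):
            counts[:, j] = _nb_draw(rng, mu_group * lib[j], truth.alpha)
            sample_ids.append(f"{g}_{r + 1}")
            sample_groups.append(g)
            j += 1

    truth.base_mean = base_mean
    truth.lib_sizes = lib
    truth.eps = eps
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=truth.gene_ids(), columns=sample_ids),
        groups=pd.Series(sample_groups, index=sample_ids, name="group"),
    )
    return cm, truth


def gen_genesets(
    n_terms: int,
    size_range: tuple[int, int] = (15, 400),
    universe: list[str] | None = None,
    truth: SynthTruth | None = None,
    *,
    n_active: int = 10,
    active_size_range: tuple[int, int] = (15, 60),
    active_purity: float = 0.9,
    namespaces: tuple[str, ...] = ("BP", "CC", "MF"),
    seed: int | None = None,
):
    """Build a gene-set collection with ``n_active`` planted coherent terms.

    Background term sizes are uniform on ``size_range`` (inclusive). Each
    active term draws ``active_purity`` of its members from planted
    differentially expressed genes of a single sign — so at least 80% of its
    members share the direction of regulation — and fills the rest from the
    universe at random. Active terms use the smaller ``active_size_range``
    because coherent pathways are small relative to the 15-400 filter window.
    """
    from .enrichment import GeneSet, GeneSetCollection

    if truth is None:
        raise ValueError("truth (with planted theta) is required to place active terms")
    if universe is None:
        universe = truth.gene_ids()
    lo, hi = size_range
    if lo > hi or lo < 1:
        raise ValueError(f"invalid size_range {size_range}")
    if hi > len(universe):
        raise ValueError(f"size_range max {hi} exceeds universe size {len(universe)}")
    if not 0.8 <= active_purity <= 1.0:
        raise ValueError("active_purity must be in [0.8, 1] to keep planted terms coherent")
    if n_active > n_terms:
        raise ValueError("n_active cannot exceed n_terms")

    rng = _rng(truth.seed if seed is None else seed, _STREAM_GENESETS)
    universe = list(universe)
    gid = np.array(universe)
    theta_by_gene = dict(zip(truth.gene_ids(), truth.theta))
    theta_u = np.array([theta_by_gene.get(g, 0.0) for g in universe])
    up_pool = gid[theta_u > 0]
    dn_pool = gid[theta_u < 0]

    terms = []
    active_ids = set()
    alo, ahi = active_size_range
    for i in range(n_terms):
        ns = namespaces[i % len(namespaces)]
        term_id = f"SYN:{i:04d}"
        if i < n_active:
            sign_pool = up_pool if rng.random() < 0.5 else dn_pool
            size = int(rng.integers(alo, ahi + 1))
            n_core = min(int(np.ceil(active_purity * size)), sign_pool.size)
            if n_core < 0.8 * size:
                raise ValueError(
                    "too few same-sign DE genes in the universe to plant a coherent "
                    f"term of size {size}; enlarge the universe or shrink active_size_range"
                )
            core = rng.choice(sign_pool, size=n_core, replace=False)
            rest_pool = np.setdiff1d(gid, core, assume_unique=False)
            rest = rng.choice(rest_pool, size=size - n_core, replace=False)
            members = frozenset(core) | frozenset(rest)
            active_ids.add(term_id)
            name = f"planted coherent term {i}"
        else:
            size = int(rng.integers(lo, hi + 1))
            members = frozenset(rng.choice(gid, size=size, replace=False))
            name = f"background term {i}"
        terms.append(GeneSet(term_id=term_id, name=name, namespace=ns, genes=members))

    truth.active_terms = active_ids
    return GeneSetCollection(terms)


# Dilution series and per-dose cohort size of the developmental screen.
SCREEN_DILUTIONS = (1.0, 0.2, 0.04, 0.008)
N_PER_DOSE = 40
CONTROL_WELLS_PER_PLATE = 8


def default_tox_curves() -> dict[str, dict[float, dict[str, float]]]:
    """True incidence probabilities emulating the screen's dose-response shape.

    The weaker mixture (A) reaches 26.5% any-effect incidence at the 0.2%
    dilution while the stronger mixture (B) reaches 67.5%, both saturate at
    the 1% exposure, and neither separates from control at the two lowest
    dilutions; the difference at 0.2% is carried mostly by the wavy-notochord
    endpoint.
    """
    return {
        "mixtureA": {
            1.0: {"mortality": 0.15, "any_effect": 1.0, "wavy_notochord": 0.10},
            0.2: {"mortality": 0.05, "any_effect": 0.265, "wavy_notochord": 0.05},
            0.04: {"mortality": 0.03, "any_effect": 0.05, "wavy_notochord": 0.01},
            0.008: {"mortality": 0.03, "any_effect": 0.04, "wavy_notochord": 0.01},
        },
        "mixtureB": {
            1.0: {"mortality": 0.20, "any_effect": 1.0, "wavy_notochord": 0.60},
            0.2: {"mortality": 0.05, "any_effect": 0.675, "wavy_notochord": 0.45},
            0.04: {"mortality": 0.03, "any_effect": 0.06, "wavy_notochord": 0.01},
            0.008: {"mortality": 0.03, "any_effect": 0.04, "wavy_notochord": 0.01},
        },
    }


def gen_toxdata(
    incidence_curves: dict[str, dict[float, dict[str, float]]] | None = None,
    n_per_dose: int = N_PER_DOSE,
    seed: int = 0,
    *,
    control_p: dict[str, float] | None = None,
    n_plates: int = 2,
) -> pd.DataFrame:
    """Draw binomial developmental-screen records plus plate-control wells.

    Returns a tidy table (treatment, dilution, endpoint, n_exposed,
    n_affected, timepoint). Control rows carry treatment ``control_negative``
    / ``control_positive`` with the ``mortality`` endpoint and 8 wells per
    plate, for plate-QC simulation, plus a vehicle-control row per endpoint.
    """
    if incidence_curves is None:
        incidence_curves = default_tox_curves()
    if n_per_dose < 1:
        raise ValueError("n_per_dose must be >= 1")
    rng = _rng(seed, _STREAM_TOX)
    control_p = {"negative": 0.02, "positive": 0.05, **(control_p or {})}

    rows = []
    endpoints = sorted({e for d in incidence_curves.values() for ep in d.values() for e in ep})
    for trt, by_dil in incidence_curves.items():
        for dil, by_ep in by_dil.items():
            for ep, p in by_ep.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"incidence probability out of [0,1]: {p}")
                k = int(rng.binomial(n_per_dose, p))
                rows.append((trt, dil, ep, n_per_dose, k, 120))
    # vehicle control arm, one cohort per endpoint
    for ep in endpoints:
        p = control_p["negative"]
        rows.append(("control", 0.0, ep, n_per_dose, int(rng.binomial(n_per_dose, p)), 120))
    # plate QC wells: 8 negative + 8 positive control fish per plate
    for plate in range(1, n_plates + 1):
        for ctype in ("negative", "positive"):
            k = int(rng.binomial(CONTROL_WELLS_PER_PLATE, control_p[ctype]))
            rows.append(
                (f"control_{ctype}_plate{plate}", 0.0, "mortality", CONTROL_WELLS_PER_PLATE, k, 120)
            )
    return pd.DataFrame(
        rows, columns=["treatment", "dilution", "endpoint", "n_exposed", "n_affected", "timepoint"]
    )


def default_pah_profile() -> dict[str, float]:
    """Per-analyte concentrations (uM at the 1% exposure scale) for site A.

    A pyrogenic-signature profile over the 33-analyte quantitative PAH panel,
    dominated by 4-5-ring parents (FLA, PYR, PHE, CHR) and summing to 190 uM;
    site B is generated as a uniform 1.63x rescaling, which reproduces the
    ~60% concentration difference with matched diagnostic ratios.
    """
    from .chemistry import PAH_PANEL

    weights = {
        "NAP": 6.0, "ACY": 1.5, "ACE": 1.2, "FLO": 2.5, "PHE": 16.0, "ANT": 2.0,
        "FLA": 22.0, "PYR": 20.0, "RET": 2.4, "BAA": 6.0, "CHR": 8.0, "BBF": 5.0,
        "BKF": 2.5, "BEP": 3.5, "BAP": 5.0, "PER": 1.0, "IPY": 2.5, "DBA": 0.6,
        "BPE": 2.8,
    }
    # remaining panel members share a small tail
    tail = [a for a in PAH_PANEL if a not in weights]
    for a in tail:
        weights[a] = 0.5
    total = sum(weights.values())
    return {a: 190.0 * w / total for a, w in weights.items()}


def gen_chemtable(
    base_profile: dict[str, float] | None = None,
    scale: float = 1.63,
    cv: float = 0.1,
    n_reps: int = 3,
    seed: int = 0,
    *,
    sample_ids: tuple[str, str] = ("siteA", "siteB"),
) -> pd.DataFrame:
    """Two PAH concentration profiles differing by ``scale`` with matched ratios.

    Replicates get multiplicative lognormal noise with the given coefficient
    of variation and mean preserved, so ``cv=0`` reproduces the profile
    exactly and diagnostic ratios agree between samples in expectation.
    """
    if base_profile is None:
        base_profile = default_pah_profile()
    if not base_profile:
        raise ValueError("base_profile must not be empty")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = _rng(seed, _STREAM_CHEM)
    sigma = np.sqrt(np.log1p(cv**2))
    rows = []
    for sample, factor in zip(sample_ids, (1.0, scale)):
        for analyte, conc in base_profile.items():
            m = conc * factor
            for rep in range(1, n_reps + 1):
                if cv == 0:
                    x = m
                else:
                    x = rng.lognormal(mean=np.log(m) - sigma**2 / 2, sigma=sigma)
                rows.append((analyte, sample, x, rep))
    return pd.DataFrame(rows, columns=["analyte", "sample", "concentration", "replicate"])
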