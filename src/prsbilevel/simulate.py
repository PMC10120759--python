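"""Synthetic-data engine for the simulation study.

Emulates the study design end-to-end at a configurable scale: blockwise
AR(1)-correlated standardized genotypes, annotation-group-structured
point-normal effects, phenotypes at fixed heritability h^2 = 0.7, and
marginal GWAS summary statistics (beta_hat = G^T y / N). The full-scale
presets are M = 125,000 SNPs, N_sumstat = 50,000 and N_test = 24,000 with
the seven annotation settings tabulated below; ``scale`` shrinks M and both
N proportionally (desk-scale default 0.02 gives M = 2,500, N_sumstat =
1,000, N_test = 480).

The genotype model is a stand-in for real biobank genotypes: per block, two
latent AR(1) Gaussian haplotypes thresholded at a drawn minor-allele
frequency yield 0/1/2 dosages, which are then column-standardized. The LD
matrix D handed to the samplers is computed from a held-out reference sample
of the same process, mirroring the use of an external reference panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .annotation import make_overlap_assignment
from .datatypes import (
    AnnotationMap,
    LDBlock,
    SummaryStats,
    ValidationError,
)

H2_DEFAULT = 0.7
M_FULL = 125_000
N_SUMSTAT_FULL = 50_000
N_TEST_FULL = 24_000


@dataclass
class SimulationSetting:
    """One row of the simulation design table.

    ``p_k`` are causal-variant percentages, ``q_k`` group percentages of the
    total heritability; ``overlap`` is "none", "overlap_I" (high IOU between
    the two zero-heritability groups) or "overlap_II" (high IOU between the
    10%/90% groups).
    """

    setting_id: int
    m_k: list[int]
    p_k: list[float]
    q_k: list[float]
    overlap: str = "none"
    h2: float = H2_DEFAULT
    n_sumstat: int = N_SUMSTAT_FULL
    n_test: int = N_TEST_FULL

    def __post_init__(self) -> None:
        if not (len(self.m_k) == len(self.p_k) == len(self.q_k)):
            raise ValidationError("m_k, p_k, q_k must have equal length")
        if abs(sum(self.q_k) - 100.0) > 1e-9:
            raise ValidationError("q_k must sum to 100")
        if any(not (0.0 < p <= 100.0) for p in self.p_k):
            raise ValidationError("p_k must lie in (0, 100]")

    @property
    def n_groups(self) -> int:
        return len(self.m_k)


SETTINGS: dict[int, SimulationSetting] = {
    1: SimulationSetting(1, [49750, 37500, 25125, 12625],
                         [0.5, 1, 1.5, 2], [0, 0, 10, 90]),
    2: SimulationSetting(2, [49750, 37500, 25125, 12625],
                         [0.5, 1, 1.5, 2], [0, 0, 50, 50]),
    3: SimulationSetting(3, [49750, 37500, 25125, 12625],
                         [0.5, 1, 1.5, 2], [10, 20, 30, 40]),
    4: SimulationSetting(4, [49750, 37500, 25125, 12625],
                         [0.5, 1, 1.5, 2], [25, 25, 25, 25]),
    5: SimulationSetting(5, [12375] * 6 + [12625, 12625, 12750, 12750],
                         [0.01] * 6 + [2, 2, 3, 3],
                         [0] * 8 + [10, 90]),
    6: SimulationSetting(6, [49750, 37500, 25125, 12625],
                         [0.5, 1, 1.5, 2], [0, 0, 10, 90], overlap="overlap_I"),
    7: SimulationSetting(7, [49750, 37500, 25125, 12625],
                         [0.5, 1, 1.5, 2], [0, 0, 10, 90], overlap="overlap_II"),
}
# Groups with q_k = 0 have no causal contribution regardless of p_k; the
# zero-heritability filler groups of setting 5 carry a nominal p_k > 0.01%
# placeholder in the table but draw all-zero effects either way.


@dataclass
class TrueEffects:
    """Per-variant true effects under the point-normal architecture."""

    beta_true: np.ndarray
    causal_mask: np.ndarray

    def __post_init__(self) -> None:
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        self.causal_mask = np.asarray(self.causal_mask, dtype=bool)
        if np.any(self.beta_true[~self.causal_mask] != 0):
            raise ValidationError("non-causal variants must have zero effect")


def _largest_remainder(sizes: list[int], total: int) -> list[int]:
    """Scale integer sizes to a new total, preserving proportions."""
    raw = [s * total / sum(sizes) for s in sizes]
    floors = [math.floor(r) for r in raw]
    remainder = total - sum(floors)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - floors[i],
                   reverse=True)
    for i in order[:remainder]:
        floors[i] += 1
    if any(f < 1 for f in floors):
        raise ValidationError("scale too small: an annotation group emptied")
    return floors


def scale_setting(setting: SimulationSetting, scale: float) -> SimulationSetting:
    """Shrink M and N proportionally, preserving p_k, q_k and relative M_k."""
    if not (0 < scale <= 1):
        raise ValidationError("scale must be in (0, 1]")
    m_total = int(round(sum(setting.m_k) * scale))
    return SimulationSetting(
        setting_id=setting.setting_id,
        m_k=_largest_remainder(setting.m_k, m_total),
        p_k=list(setting.p_k),
        q_k=list(setting.q_k),
        overlap=setting.overlap,
        h2=setting.h2,
        n_sumstat=int(round(setting.n_sumstat * scale)),
        n_test=int(round(setting.n_test * scale)),
    )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeModel:
    """Blockwise thresholded-Gaussian-haplotype genotype process."""

    maf: np.ndarray
    block_bounds: list[tuple[int, int]]
    rho: float
    tau: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.maf = np.asarray(self.maf, dtype=float)
        self.tau = norm.ppf(self.maf)

    @property
    def n_variants(self) -> int:
        return len(self.maf)

    def _latent(self, n: int, size: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((n, size))
        if self.rho > 0:
            w = math.sqrt(1.0 - self.rho**2)
            for j in range(1, size):
                z[:, j] = self.rho * z[:, j - 1] + w * z[:, j]
        return z

    def sample_dosages(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw 0/1/2 allele counts for n individuals."""
        out = np.empty((n, self.n_variants))
        for lo, hi in self.block_bounds:
            t = self.tau[lo:hi]
            h1 = self._latent(n, hi - lo, rng) < t
            h2 = self._latent(n, hi - lo, rng) < t
            out[:, lo:hi] = h1.astype(float) + h2.astype(float)
        return out


def _standardize(g: np.ndarray) -> np.ndarray:
    g = g - g.mean(axis=0)
    sd = g.std(axis=0)
    sd[sd == 0] = 1.0
    return g / sd


def variant_names(m: int, prefix: str = "v") -> list[str]:
    width = max(6, len(str(m)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(m)]


def make_genotypes(
    n: int,
    m: int,
    block_size: int = 500,
    rho: float = 0.7,
    maf_range: tuple[float, float] = (0.01, 0.5),
    seed: int = 0,
    n_ref: int = 500,
):
    """Simulate standardized genotypes plus a reference-panel LD estimate.

    Returns ``(G, blocks, model)``: G is the (n, m) standardized cohort
    matrix; ``blocks`` are LDBlock objects whose D is the sample correlation
    in an independent reference draw of ``n_ref`` individuals from the same
    process (not the cohort itself).
    """
    if not (0.0 <= rho < 1.0):
        raise ValidationError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(maf_range[0], maf_range[1], size=m)
    bounds = [(lo, min(lo + block_size, m)) for lo in range(0, m, block_size)]
    model = GenotypeModel(maf=maf, block_bounds=bounds, rho=rho)

    ref = model.sample_dosages(n_ref, rng)
    # a monomorphic reference column has undefined correlation; jitter it
    mono = ref.std(axis=0) == 0
    if mono.any():
        ref[:, mono] += 1e-6 * rng.standard_normal((n_ref, int(mono.sum())))

    names = variant_names(m)
    blocks = []
    for lo, hi in bounds:
        D = np.atleast_2d(np.corrcoef(ref[:, lo:hi], rowvar=False))
        blocks.append(LDBlock(names[lo:hi], D))

    G = _standardize(model.sample_dosages(n, rng))
    return G, blocks, model


# ---------------------------------------------------------------------------
# effects / phenotypes / GWAS
# ---------------------------------------------------------------------------

def dominant_group(am: AnnotationMap, setting: SimulationSetting,
                   variant_id: str) -> int:
    """Group index whose variance applies to a (possibly multi-annotated)
    variant: the member group with the largest heritability share q_k."""
    labels = am.labels_for(variant_id)
    idx = [am.groups.index(g) for g in labels]
    return max(idx, key=lambda k: setting.q_k[k])


def draw_effects(setting: SimulationSetting, am: AnnotationMap,
                 variant_ids: list[str], seed: int = 0,
                 variance_mode: str = "printed") -> TrueEffects:
    """Point-normal effects: causal with probability p_{A_j}, then
    N(0, q_{A_j} h^2 / (p_{A_j} M)).

    ``variance_mode="group_normalized"`` substitutes M_k for M in the
    denominator so each group's expected heritability contribution is
    proportional to q_k alone rather than q_k * M_k / M.
    """
    if variance_mode not in ("printed", "group_normalized"):
        raise ValidationError(f"unknown variance_mode {variance_mode!r}")
    rng = np.random.default_rng(seed)
    m = len(variant_ids)
    beta = np.zeros(m)
    causal = np.zeros(m, dtype=bool)
    group_of = np.array([dominant_group(am, setting, v) for v in variant_ids])
    for k in range(setting.n_groups):
        members = np.flatnonzero(group_of == k)
        if members.size == 0:
            continue
        p = setting.p_k[k] / 100.0
        q = setting.q_k[k] / 100.0
        denom = m if variance_mode == "printed" else members.size
        var = q * setting.h2 / (p * denom)
        mask = rng.random(members.size) < p
        causal[members] = mask
        if var > 0:
            beta[members[mask]] = rng.normal(0.0, math.sqrt(var),
                                             size=int(mask.sum()))
    causal &= beta != 0  # zero-variance groups contribute no causal effects
    return TrueEffects(beta_true=beta, causal_mask=causal)


def true_per_snp_h2(setting: SimulationSetting, am: AnnotationMap,
                    variant_ids: list[str],
                    variance_mode: str = "printed") -> np.ndarray:
    """Expected per-SNP heritability q_{A_j} h^2 / M (the point-normal
    E[beta_j^2]); used as the oracle input for the functional-prior
    comparator."""
    m = len(variant_ids)
    out = np.empty(m)
    group_of = [dominant_group(am, setting, v) for v in variant_ids]
    sizes = np.bincount(group_of, minlength=setting.n_groups)
    for j, k in enumerate(group_of):
        denom = m if variance_mode == "printed" else sizes[k]
        out[j] = (setting.q_k[k] / 100.0) * setting.h2 / denom
    return out


def make_phenotype(G: np.ndarray, effects: TrueEffects, h2: float,
                   seed: int = 0) -> np.ndarray:
    """y = G beta + eps with the realized genetic-variance fraction fixed to
    h2 exactly in-sample (noise drawn orthogonal to G beta, then scaled);
    the returned y is standardized."""
    if not (0.0 < h2 < 1.0):
        raise ValidationError("h2 must lie in the open interval (0, 1)")
    g = np.asarray(G, dtype=float) @ effects.beta_true
    var_g = g.var()
    if var_g == 0:
        raise ValidationError("G beta is constant (no causal variants)")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(g.size)
    eps -= eps.mean()
    g_c = g - g.mean()
    eps -= (eps @ g_c) / (g_c @ g_c) * g_c  # exact in-sample orthogonality
    eps *= math.sqrt(var_g * (1.0 - h2) / h2) / eps.std()
    y = g + eps
    return (y - y.mean()) / y.std()


def marginal_gwas(G: np.ndarray, y: np.ndarray,
                  variant_ids: list[str] | None = None) -> SummaryStats:
    """Marginal GWAS on standardized data: beta_hat = G^T y / N."""
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    beta_hat = G.T @ y / n
    ids = variant_ids if variant_ids is not None else variant_names(G.shape[1])
    table = pd.DataFrame({
        "variant_id": ids,
        "chrom": "1",
        "pos": np.arange(1, G.shape[1] + 1),
        "a1": "A",
        "a2": "G",
        "beta_hat": beta_hat,
    })
    return SummaryStats(table, n)


# ---------------------------------------------------------------------------
# full experiment bundle
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """Everything one simulated replicate produces."""

    setting: SimulationSetting
    annotations: AnnotationMap
    sumstats: SummaryStats
    blocks: list[LDBlock]
    effects: TrueEffects
    G_test: np.ndarray  # standardized test genotypes
    y_test: np.ndarray
    test_dosages: np.ndarray  # raw 0/1/2 counts (for PLINK export)
    variant_ids: list[str]
    maf: np.ndarray


def run_setting(setting_id: int, scale: float = 0.02, seed: int = 0,
                rho: float = 0.7, block_size: int = 500,
                target_iou: float = 0.5,
                variance_mode: str = "printed") -> StudyBundle:
    """Simulate one full replicate of a tabulated setting.

    All table proportions (p_k, q_k, relative M_k) are preserved under
    scaling; the LD block size scales with the genome (floor 25 SNPs),
    treating the reduced genome as proportionally thinned. Deterministic
    given ``seed``.
    """
    if setting_id not in SETTINGS:
        raise ValidationError(f"unknown setting {setting_id}")
    setting = scale_setting(SETTINGS[setting_id], scale)
    am = make_overlap_assignment(setting.m_k, pattern=setting.overlap,
                                 target_iou=target_iou, seed=seed)
    m = len(am.assignment)
    names = variant_names(m)

    bs = max(25, int(round(block_size * scale)))
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.01, 0.5, size=m)
    bounds = [(lo, min(lo + bs, m)) for lo in range(0, m, bs)]
    model = GenotypeModel(maf=maf, block_bounds=bounds, rho=rho)

    ref = model.sample_dosages(500, rng)
    mono = ref.std(axis=0) == 0
    if mono.any():
        ref[:, mono] += 1e-6 * rng.standard_normal((500, int(mono.sum())))
    blocks = [LDBlock(names[lo:hi],
                      np.atleast_2d(np.corrcoef(ref[:, lo:hi], rowvar=False)))
              for lo, hi in bounds]

    effects = draw_effects(setting, am, names, seed=seed,
                           variance_mode=variance_mode)
    G_sum = _standardize(model.sample_dosages(setting.n_sumstat, rng))
    y_sum = make_phenotype(G_sum, effects, setting.h2, seed=seed + 1)
    ss = marginal_gwas(G_sum, y_sum, names)
    del G_sum

    test_dosages = model.sample_dosages(setting.n_test, rng)
    G_test = _standardize(test_dosages)
    y_test = make_phenotype(G_test, effects, setting.h2, seed=seed + 2)

    return StudyBundle(setting=setting, annotations=am, sumstats=ss,
                       blocks=blocks, effects=effects, G_test=G_test,
                       y_test=y_test, test_dosages=test_dosages,
                       variant_ids=names, maf=maf)
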