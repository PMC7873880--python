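"""Single-QTN additive trait-pair simulation under four genetic architectures.

Each trait in a pair is controlled by exactly one additive QTN.  The four
architectures differ only in how the two causal markers are chosen:

* ``independent`` — the two QTNs sit on different chromosomes;
* ``ld_direct``   — same chromosome, with the pairwise r2 between the QTNs
  bounded above by a chosen threshold (and pushed as close to it as the
  panel allows);
* ``ld_indirect`` — a common "middle" marker is chosen by MAF and each QTN
  is picked to maximize its r2 with that middle marker under the bound,
  one upstream and one downstream; the middle marker stays in the GWAS
  marker set;
* ``pleiotropic`` — a single QTN controls both traits.

Phenotypes are genetic value plus Gaussian noise whose variance is set so
the in-sample heritability Var(g)/(Var(g) + sd^2) equals the input exactly.
QTN markers are removed from the marker set handed to the GWAS (the causal
variant is typically not genotyped), and a fresh QTN pair is drawn for
every replicate.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from pleiolink.genotypes import GenotypeMatrix, pairwise_r2

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "QTNAssignment",
    "TraitPair",
    "maf_candidates",
    "select_qtns_independent",
    "select_qtns_ld_direct",
    "select_qtns_ld_indirect",
    "select_qtn_pleiotropic",
    "simulate_trait",
    "simulate_replicate",
    "replicate_rng",
]

ARCHITECTURES = ("independent", "ld_direct", "ld_indirect", "pleiotropic")

#: how far (in marker indices, same chromosome) the LD-pair search looks
LD_SEARCH_WINDOW = 100
_MAX_RETRIES = 100


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation design grid."""

    architecture: str
    maf_target: float
    h2_pair: tuple[float, float]
    n_individuals: int
    species_profile: str
    detection_window_bp: float
    ld_max: float | None = None  # only meaningful for the two ld architectures
    additive_effect: float = 0.10
    fdr_level: float = 0.10
    n_replicates: int = 100
    residual_correlation: float = 0.0  # hook; the study design uses 0
    pleiotropy_sign: float = 1.0  # sign of the QTN effect on trait 2 under pleiotropy
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.architecture.startswith("ld_"):
            if self.ld_max is None or not 0.0 < self.ld_max < 1.0:
                raise ValueError("ld architectures need ld_max in (0, 1)")
        if not all(0.0 < h <= 1.0 for h in self.h2_pair):
            raise ValueError("heritabilities must be in (0, 1]")
        if not 0.0 < self.maf_target <= 0.5:
            raise ValueError("maf_target must be in (0, 0.5]")
        if self.detection_window_bp <= 0:
            raise ValueError("detection window must be positive")

    def key(self) -> str:
        """Canonical identity string (drives per-scenario seeding)."""
        return (
            f"{self.architecture}|ld={self.ld_max}|maf={self.maf_target}|"
            f"h2={self.h2_pair[0]},{self.h2_pair[1]}|n={self.n_individuals}|"
            f"{self.species_profile}"
        )


@dataclass
class QTNAssignment:
    """The causal markers drawn for one replicate."""

    idx1: int
    idx2: int
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    realized_maf_1: float
    realized_maf_2: float
    realized_r2: float  # NaN under pleiotropy (self-LD is not meaningful)
    middle_idx: int | None = None  # indirect architecture only


@dataclass
class TraitPair:
    """Two simulated phenotypes with their underlying genetic values."""

    y1: np.ndarray
    y2: np.ndarray
    g1: np.ndarray
    g2: np.ndarray
    h2_in: tuple[float, float]
    residual_sd_1: float
    residual_sd_2: float


def maf_candidates(
    G: GenotypeMatrix, maf_target: float, tol: float = 0.02
) -> np.ndarray:
    """Indices of markers with MAF within ``tol`` of the target.

    If no marker qualifies the tolerance is doubled (with a log note) until
    the set is non-empty.
    """
    maf = G.maf()
    poly = maf > 0
    if not poly.any():
        raise ValueError("panel has no polymorphic markers")
    while True:
        idx = np.flatnonzero(poly & (np.abs(maf - maf_target) <= tol + 1e-12))
        if idx.size:
            return idx
        tol *= 2
        logger.info("no markers near MAF %.3f; widening tolerance to %.3f", maf_target, tol)


def _marker_info(G: GenotypeMatrix, j: int) -> tuple[str, int]:
    row = G.marker_map.iloc[j]
    return str(row["chrom"]), int(row["pos"])


def _assignment(G: GenotypeMatrix, j1: int, j2: int, middle: int | None = None) -> QTNAssignment:
    maf = G.maf()
    c1, p1 = _marker_info(G, j1)
    c2, p2 = _marker_info(G, j2)
    r2 = np.nan if j1 == j2 else pairwise_r2(G.dosages[:, j1], G.dosages[:, j2])
    return QTNAssignment(
        idx1=int(j1), idx2=int(j2), chrom1=c1, pos1=p1, chrom2=c2, pos2=p2,
        realized_maf_1=float(maf[j1]), realized_maf_2=float(maf[j2]),
        realized_r2=r2, middle_idx=None if middle is None else int(middle),
    )


def select_qtns_independent(
    G: GenotypeMatrix, maf_target: float, rng: np.random.Generator
) -> QTNAssignment:
    """Two QTNs drawn by MAF, resampled until they land on different chromosomes."""
    cand = maf_candidates(G, maf_target)
    chroms = G.marker_map["chrom"].to_numpy()
    if len(set(chroms[cand])) < 2:
        raise ValueError("MAF candidates span a single chromosome; cannot place independent QTNs")
    for _ in range(_MAX_RETRIES):
        j1, j2 = rng.choice(cand, size=2, replace=False)
        if chroms[j1] != chroms[j2]:
            return _assignment(G, j1, j2)
    raise RuntimeError("failed to draw QTNs on different chromosomes")


def _r2_with(G: GenotypeMatrix, j: int, others: np.ndarray) -> np.ndarray:
    """r2 between marker j and each marker in ``others`` (NaN if monomorphic)."""
    d = G.dosages.astype(float)
    x = d[:, j] - d[:, j].mean()
    sx = np.sqrt((x * x).sum())
    block = d[:, others] - d[:, others].mean(axis=0)
    denom = np.sqrt((block * block).sum(axis=0)) * sx
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x @ block) / denom
    return r * r


def _argmax_under_bound(
    G: GenotypeMatrix, anchor: int, others: np.ndarray, r2_max: float
) -> tuple[int, float] | None:
    """Marker in ``others`` maximizing r2 with ``anchor`` subject to r2 <= bound.

    Ties broken by smaller physical distance to the anchor, then lower index.
    """
    if others.size == 0:
        return None
    r2 = _r2_with(G, anchor, others)
    ok = np.isfinite(r2) & (r2 <= r2_max)
    if not ok.any():
        return None
    others, r2 = others[ok], r2[ok]
    pos = G.marker_map["pos"].to_numpy()
    dist = np.abs(pos[others] - pos[anchor])
    order = np.lexsort((others, dist, -r2))  # r2 desc, then distance, then index
    best = order[0]
    return int(others[best]), float(r2[best])


def _same_chrom_window(G: GenotypeMatrix, j: int) -> np.ndarray:
    """Indices on j's chromosome within +/- LD_SEARCH_WINDOW marker positions."""
    chroms = G.marker_map["chrom"].to_numpy()
    lo, hi = max(0, j - LD_SEARCH_WINDOW), j + LD_SEARCH_WINDOW + 1
    idx = np.arange(lo, min(hi, G.n_markers))
    return idx[(chroms[idx] == chroms[j]) & (idx != j)]


def select_qtns_ld_direct(
    G: GenotypeMatrix, maf_target: float, r2_max: float, rng: np.random.Generator
) -> QTNAssignment:
    """QTN1 by MAF; QTN2 = same-chromosome marker maximizing r2 under the bound."""
    if not 0.0 < r2_max < 1.0:
        raise ValueError("r2_max must be in (0, 1)")
    cand = maf_candidates(G, maf_target)
    for _ in range(_MAX_RETRIES):
        j1 = int(rng.choice(cand))
        found = _argmax_under_bound(G, j1, _same_chrom_window(G, j1), r2_max)
        if found is not None:
            return _assignment(G, j1, found[0])
    raise RuntimeError(f"no same-chromosome partner with r2 <= {r2_max} found")


def select_qtns_ld_indirect(
    G: GenotypeMatrix, maf_target: float, r2_max: float, rng: np.random.Generator
) -> QTNAssignment:
    """Middle marker by MAF; QTNs flank it, each maximizing r2 with it under the bound.

    The LD bound constrains r2(QTN, middle); the r2 between the two QTNs is
    recorded but not itself bounded.  The middle marker is retained in the
    GWAS marker set (it is not causal).
    """
    if not 0.0 < r2_max < 1.0:
        raise ValueError("r2_max must be in (0, 1)")
    cand = maf_candidates(G, maf_target)
    pos = G.marker_map["pos"].to_numpy()
    for _ in range(_MAX_RETRIES):
        m = int(rng.choice(cand))
        window = _same_chrom_window(G, m)
        up = _argmax_under_bound(G, m, window[pos[window] < pos[m]], r2_max)
        down = _argmax_under_bound(G, m, window[pos[window] > pos[m]], r2_max)
        if up is not None and down is not None:
            return _assignment(G, up[0], down[0], middle=m)
    raise RuntimeError(f"no flanking markers with r2 <= {r2_max} around any middle marker")


def select_qtn_pleiotropic(
    G: GenotypeMatrix, maf_target: float, rng: np.random.Generator
) -> QTNAssignment:
    """One MAF-selected marker controlling both traits."""
    cand = maf_candidates(G, maf_target)
    j = int(rng.choice(cand))
    return _assignment(G, j, j)


def simulate_trait(
    x: np.ndarray, additive_effect: float, h2: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """Additive single-QTN phenotype with exact in-sample heritability.

    g = additive_effect * x;  residual sd = sqrt(Var(g) (1 - h2) / h2) with
    the sample variance of g; y = g + N(0, sd).  h2 = 1 returns y = g.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("QTN dosage vector is constant; heritability undefined")
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must be in (0, 1]")
    g = additive_effect * x
    var_g = g.var(ddof=1)
    residual_sd = float(np.sqrt(var_g * (1.0 - h2) / h2))
    y = g + rng.normal(0.0, residual_sd, size=len(g)) if residual_sd > 0 else g.copy()
    return y, g, residual_sd


def replicate_rng(scenario: ScenarioConfig, replicate_index: int) -> np.random.Generator:
    """Reproducible per-replicate stream: study seed -> scenario hash -> replicate.

    Any replicate can be regenerated in isolation, and results do not
    depend on execution order across scenarios or workers.
    """
    digest = hashlib.sha256(scenario.key().encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    ss = np.random.SeedSequence([int(scenario.seed), *words, int(replicate_index)])
    return np.random.default_rng(ss)


_SELECTORS = {
    "independent": lambda G, sc, rng: select_qtns_independent(G, sc.maf_target, rng),
    "ld_direct": lambda G, sc, rng: select_qtns_ld_direct(G, sc.maf_target, sc.ld_max, rng),
    "ld_indirect": lambda G, sc, rng: select_qtns_ld_indirect(G, sc.maf_target, sc.ld_max, rng),
    "pleiotropic": lambda G, sc, rng: select_qtn_pleiotropic(G, sc.maf_target, rng),
}


def simulate_replicate(
    scenario: ScenarioConfig, G: GenotypeMatrix, replicate_index: int
) -> tuple[TraitPair, QTNAssignment, GenotypeMatrix]:
    """One replicate: draw QTNs, simulate the trait pair, drop the QTN markers.

    Residuals of the two traits are drawn independently (the default study
    design has zero residual correlation); ``residual_correlation`` in the
    scenario installs a bivariate-normal residual if nonzero.
    """
    if replicate_index >= scenario.n_replicates:
        raise ValueError("replicate_index out of range")
    rng = replicate_rng(scenario, replicate_index)
    qtn = _SELECTORS[scenario.architecture](G, scenario, rng)

    x1 = G.dosages[:, qtn.idx1].astype(float)
    x2 = G.dosages[:, qtn.idx2].astype(float)
    eff2 = scenario.additive_effect * (
        scenario.pleiotropy_sign if scenario.architecture == "pleiotropic" else 1.0
    )
    y1, g1, sd1 = simulate_trait(x1, scenario.additive_effect, scenario.h2_pair[0], rng)
    y2, g2, sd2 = simulate_trait(x2, eff2, scenario.h2_pair[1], rng)
    rho = scenario.residual_correlation
    if rho != 0.0 and sd1 > 0 and sd2 > 0:
        e1 = (y1 - g1) / sd1
        e2 = (y2 - g2) / sd2
        y2 = g2 + sd2 * (rho * e1 + np.sqrt(1.0 - rho * rho) * e2)

    drop = {qtn.idx1, qtn.idx2}
    markers = G.drop_markers(sorted(drop))
    pair = TraitPair(y1, y2, g1, g2, tuple(scenario.h2_pair), sd1, sd2)
    return pair, qtn, markers
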