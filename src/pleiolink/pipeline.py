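"""Design-grid enumeration and end-to-end scenario orchestration.

The full study design crosses six architecture variants (independent QTNs;
direct and indirect LD control at each of two thresholds; one pleiotropic
QTN) with two QTN MAF targets, three heritability pairs, three sample
sizes, and two species LD profiles — 216 scenarios, each replicated with a
fresh QTN draw.  Seeds derive from scenario identity, so results are
independent of execution order and worker count.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from pleiolink.detect import (
    DetectionOutcome,
    DetectionSummary,
    score_replicate,
    summarize_scenario,
)
from pleiolink.genotypes import (
    PROFILES,
    GenotypeMatrix,
    filter_markers,
    generate_genotypes,
    nested_subsample,
)
from pleiolink.mlm import (
    kinship_eigendecomposition,
    multivariate_scan,
    univariate_scan,
    vanraden_kinship,
)
from pleiolink.traits import ScenarioConfig, simulate_replicate

logger = logging.getLogger(__name__)

__all__ = [
    "StudyDesign",
    "ScenarioResult",
    "paper_design",
    "reduced_design",
    "enumerate_scenarios",
    "build_panels",
    "run_scenario",
    "run_study",
    "design_from_yaml",
    "design_to_yaml",
]


@dataclass
class StudyDesign:
    """The factor levels of the simulation grid plus panel-generation knobs."""

    architectures: tuple[str, ...] = ("independent", "ld_direct", "ld_indirect", "pleiotropic")
    ld_thresholds: tuple[float, ...] = (0.01, 0.98)
    maf_targets: tuple[float, ...] = (0.05, 0.40)
    h2_pairs: tuple[tuple[float, float], ...] = ((0.30, 0.30), (0.30, 0.80), (0.80, 0.80))
    sample_sizes: tuple[int, ...] = (500, 1000, 2815)
    species_profiles: tuple[str, ...] = ("maize-like", "soybean-like")
    windows_bp: dict = field(
        default_factory=lambda: {"maize-like": 10_000.0, "soybean-like": 1_000_000.0}
    )
    alternate_windows_bp: dict = field(
        default_factory=lambda: {"maize-like": 1_000.0, "soybean-like": 10_000.0}
    )
    fdr_levels: tuple[float, ...] = (0.10, 0.05)
    n_replicates: int = 100
    master_seed: int = 0
    # synthetic-panel size (markers = n_chromosomes x markers_per_chromosome)
    n_chromosomes: int = 4
    markers_per_chromosome: int = 500

    def __post_init__(self) -> None:
        for name in ("architectures", "maf_targets", "h2_pairs", "sample_sizes",
                     "species_profiles", "fdr_levels"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")


def paper_design(master_seed: int = 0) -> StudyDesign:
    """The full 216-scenario grid at 100 replicates."""
    return StudyDesign(master_seed=master_seed)


def reduced_design(master_seed: int = 0) -> StudyDesign:
    """A desk-scale grid: one sample size, one MAF, one heritability pair,
    maize-like panels, 20 replicates."""
    return StudyDesign(
        maf_targets=(0.40,),
        h2_pairs=((0.80, 0.80),),
        sample_sizes=(500,),
        species_profiles=("maize-like",),
        fdr_levels=(0.10,),
        n_replicates=20,
        master_seed=master_seed,
    )


def enumerate_scenarios(design: StudyDesign) -> list[ScenarioConfig]:
    """Deterministic full cross of the design grid.

    LD thresholds expand only inside the two LD architectures; windows and
    FDR levels are evaluation settings (each scenario carries its species'
    default window and the first FDR level).
    """
    scenarios = []
    for arch in design.architectures:
        thresholds = design.ld_thresholds if arch.startswith("ld_") else (None,)
        for ld_max in thresholds:
            for maf in design.maf_targets:
                for h2 in design.h2_pairs:
                    for n in design.sample_sizes:
                        for species in design.species_profiles:
                            scenarios.append(
                                ScenarioConfig(
                                    architecture=arch,
                                    ld_max=ld_max,
                                    maf_target=maf,
                                    h2_pair=tuple(h2),
                                    n_individuals=n,
                                    species_profile=species,
                                    detection_window_bp=design.windows_bp[species],
                                    fdr_level=design.fdr_levels[0],
                                    n_replicates=design.n_replicates,
                                    seed=design.master_seed,
                                )
                            )
    return scenarios


def build_panels(design: StudyDesign) -> dict[tuple[str, int], GenotypeMatrix]:
    """One filtered panel per (species profile, sample size).

    For each species a single panel is generated at the largest sample size
    and the smaller sizes are nested random subsamples of it (markers are
    re-filtered per subsample since MAF and MAC shift with the sample).
    """
    panels: dict[tuple[str, int], GenotypeMatrix] = {}
    sizes = sorted(set(design.sample_sizes), reverse=True)
    for species in design.species_profiles:
        profile = PROFILES[species]
        import hashlib

        word = int.from_bytes(
            hashlib.sha256(f"panel|{species}".encode()).digest()[:4], "little"
        )
        seed = int(
            np.random.SeedSequence([design.master_seed, word]).generate_state(1)[0]
            % (2**31)
        )
        G = generate_genotypes(
            sizes[0],
            design.n_chromosomes,
            design.markers_per_chromosome,
            profile,
            inbreeding=1.0,
            seed=seed,
        )
        subs = nested_subsample(G, sizes, seed=seed + 1)
        for n, sub in zip(sizes, subs):
            panels[(species, n)] = filter_markers(sub)
    return panels


@dataclass
class ScenarioResult:
    scenario: ScenarioConfig
    summaries: list[DetectionSummary]
    outcomes: list[DetectionOutcome]
    qtn_table: pd.DataFrame
    n_invalid: int = 0


def run_scenario(
    scenario: ScenarioConfig,
    panel: GenotypeMatrix,
    uni_mode: str = "per_snp_ml",
    multi_mode: str = "null_based",
    max_invalid_fraction: float = 0.05,
) -> ScenarioResult:
    """All replicates of one scenario: QTN draw -> traits -> three scans -> scoring.

    The kinship (and its eigendecomposition, and the rotated marker matrix)
    is computed once from the full filtered panel; removing the <= 2 QTN
    columns per replicate reuses the cached rotation.  Replicate-level
    failures are logged and skipped; the scenario fails if more than
    ``max_invalid_fraction`` of replicates are invalid.
    """
    K = vanraden_kinship(panel)
    eig = kinship_eigendecomposition(K)
    d, U = eig
    R_full = (U.T @ panel.dosages.astype(float)).T  # (m, n)

    outcomes: list[DetectionOutcome] = []
    qtn_rows = []
    n_invalid = 0
    for r in range(scenario.n_replicates):
        try:
            pair, qtn, markers = simulate_replicate(scenario, panel, r)
            keep = np.setdiff1d(np.arange(panel.n_markers), [qtn.idx1, qtn.idx2])
            R = R_full[keep]
            scans = {
                "univariate_trait1": univariate_scan(
                    pair.y1, markers, K, mode=uni_mode, eig=eig,
                    model_tag="univariate_trait1", rotated_markers=R,
                ),
                "univariate_trait2": univariate_scan(
                    pair.y2, markers, K, mode=uni_mode, eig=eig,
                    model_tag="univariate_trait2", rotated_markers=R,
                ),
                "multivariate": multivariate_scan(
                    np.column_stack([pair.y1, pair.y2]), markers, K,
                    mode=multi_mode, eig=eig, rotated_markers=R,
                ),
            }
            outcomes.extend(
                score_replicate(
                    scans, qtn, scenario.detection_window_bp, scenario.fdr_level
                )
            )
            qtn_rows.append(
                {
                    "replicate": r,
                    "chrom1": qtn.chrom1, "pos1": qtn.pos1, "maf1": qtn.realized_maf_1,
                    "chrom2": qtn.chrom2, "pos2": qtn.pos2, "maf2": qtn.realized_maf_2,
                    "r2": qtn.realized_r2,
                }
            )
        except Exception:
            logger.exception("replicate %d of %s failed", r, scenario.key())
            n_invalid += 1
    if n_invalid > max_invalid_fraction * scenario.n_replicates:
        raise RuntimeError(
            f"{n_invalid}/{scenario.n_replicates} replicates invalid for {scenario.key()}"
        )
    summaries = summarize_scenario(outcomes, scenario)
    return ScenarioResult(scenario, summaries, outcomes, pd.DataFrame(qtn_rows), n_invalid)


def _result_rows(res: ScenarioResult) -> list[dict]:
    rows = []
    sc = res.scenario
    for s in res.summaries:
        for stat_name, value in (
            ("rate_t1", s.rate_t1),
            ("rate_t2", s.rate_t2),
            ("rate_both", s.rate_both),
            ("error_rate", s.error_rate),
        ):
            rows.append(
                {
                    "architecture": sc.architecture,
                    "ld_max": sc.ld_max,
                    "maf_target": sc.maf_target,
                    "h2_t1": sc.h2_pair[0],
                    "h2_t2": sc.h2_pair[1],
                    "n_individuals": sc.n_individuals,
                    "species": sc.species_profile,
                    "window_bp": sc.detection_window_bp,
                    "fdr_level": sc.fdr_level,
                    "model": s.model,
                    "label": s.label,
                    "statistic": stat_name,
                    "rate": value,
                    "n_replicates": s.n_replicates,
                }
            )
    return rows


def run_study(
    design: StudyDesign,
    n_workers: int = 1,
    out_dir: str | None = None,
    uni_mode: str = "per_snp_ml",
    multi_mode: str = "null_based",
) -> pd.DataFrame:
    """Map :func:`run_scenario` over the grid; long table of rates.

    Worker count cannot change results: every replicate's stream derives
    from (master seed, scenario identity, replicate index).  Failed
    scenarios are recorded in the manifest and omitted from the table.
    """
    scenarios = enumerate_scenarios(design)
    if not scenarios:
        logger.warning("empty design; nothing to run")
        return pd.DataFrame()
    panels = build_panels(design)

    def one(sc: ScenarioConfig):
        try:
            return _result_rows(
                run_scenario(sc, panels[(sc.species_profile, sc.n_individuals)],
                             uni_mode=uni_mode, multi_mode=multi_mode)
            )
        except Exception as exc:  # noqa: BLE001 - record and continue
            logger.exception("scenario failed: %s", sc.key())
            return [{"architecture": sc.architecture, "error": str(exc)}]

    if n_workers > 1:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=n_workers)(delayed(one)(sc) for sc in scenarios)
    else:
        chunks = [one(sc) for sc in scenarios]

    rows = [row for chunk in chunks for row in chunk]
    table = pd.DataFrame(rows)
    failed = table[table.get("error").notna()] if "error" in table else pd.DataFrame()
    if "error" in table:
        table = table[table["error"].isna()].drop(columns=["error"])

    if out_dir is not None:
        import json
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "detection_rates.tsv", sep="\t", index=False)
        manifest = {
            "design": _design_dict(design),
            "n_scenarios": len(scenarios),
            "n_failed": int(len(failed)),
            "failed": failed.to_dict("records") if len(failed) else [],
            "versions": {"pleiolink": "0.1.0", "numpy": np.__version__},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return table


def _design_dict(design: StudyDesign) -> dict:
    d = asdict(design)
    d["h2_pairs"] = [list(p) for p in design.h2_pairs]
    for k in ("architectures", "ld_thresholds", "maf_targets", "sample_sizes",
              "species_profiles", "fdr_levels"):
        d[k] = list(d[k])
    return d


def design_to_yaml(design: StudyDesign, path: str) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(_design_dict(design), f, sort_keys=False)


def design_from_yaml(path: str) -> StudyDesign:
    with open(path) as f:
        raw = yaml.safe_load(f)
    raw["h2_pairs"] = tuple(tuple(p) for p in raw["h2_pairs"])
    for k in ("architectures", "ld_thresholds", "maf_targets", "sample_sizes",
              "species_profiles", "fdr_levels"):
        if k in raw:
            raw[k] = tuple(raw[k])
    return StudyDesign(**raw)
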