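"""Generate the two synthetic genotype panels and verify their LD-decay contrast.

Builds a maize-like panel (rapid LD decay, GBS-style clustered markers) and
a soybean-like panel (long-range LD, array-style spacing) of 500 inbred
lines x 4 chromosomes x 500 markers, applies the standard marker filters
(MAC >= 5, pairwise pruning at r2 = 0.9), and writes each panel's LD-decay
table.  The headline check: mean r2 falls to ~0.10 by ~10 kb in the
maize-like panel and by ~1 Mb in the soybean-like panel — the distances the
detection windows are calibrated to.

Outputs: results/ld_decay_<species>.tsv; PLINK panels under scratch/.
"""

import pathlib

import numpy as np

from pleiolink.genotypes import PROFILES, filter_markers, generate_genotypes, ld_decay_curve, write_panel

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"
SCRATCH = pathlib.Path(__file__).resolve().parents[1] / "scratch"
SEED = 1

BINS = {
    "maize-like": np.array([0, 2e3, 5e3, 8e3, 12e3, 20e3, 50e3, 100e3, 300e3, 1e6]),
    "soybean-like": np.array([0, 1e5, 3e5, 6e5, 8e5, 1.2e6, 2e6, 4e6, 8e6]),
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    for name, profile in PROFILES.items():
        G = generate_genotypes(500, 4, 500, profile, seed=SEED)
        Gf = filter_markers(G)
        tab = ld_decay_curve(Gf, BINS[name], max_pairs=200_000, seed=SEED)
        slug = name.split("-")[0]
        tab.to_csv(RESULTS / f"ld_decay_{slug}.tsv", sep="\t", index=False)
        write_panel(Gf, str(SCRATCH / f"panel_{slug}"))
        below = tab.loc[tab["mean_r2"] <= 0.10, "bin_mid"]
        first = below.iloc[0] if len(below) else float("nan")
        print(
            f"{name}: {G.n_markers} -> {Gf.n_markers} markers after filtering; "
            f"mean r2 first drops to <= 0.10 in the bin centered at {first:,.0f} bp "
            f"(calibration target {profile.target_decay_distance_bp:,.0f} bp)"
        )


if __name__ == "__main__":
    main()
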