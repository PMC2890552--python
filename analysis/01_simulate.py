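#!/usr/bin/env python
"""Generate the synthetic study: one balanced 16-chip dye-swap experiment
plus SNP, GO, qPCR and ONL inputs, all with ground truth.

Writes a runnable dataset directory under results/sim/ that the later
numbered scripts consume. Every file is regenerated deterministically from
the seed below.
"""

from pathlib import Path

from retqtl import io_formats, synthetic_data as sim

SEED = 11
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"


def main() -> None:
    chips, design, truth = sim.gen_two_color_experiment(n_genes=500, seed=SEED)
    sim.write_experiment(OUT, chips, design, truth)
    print(f"two-color experiment: {len(chips)} chips x "
          f"{len(chips[0].spots)} spots -> {OUT}")

    snps, snp_truth = sim.gen_snp_table(n_genes=100, pass_frac=0.3, seed=SEED)
    io_formats.write_snp_table(snps, OUT / "snps.csv")
    snp_truth.to_json(OUT / "snp_truth.json")
    print(f"SNP table: {len(snps)} records, "
          f"{len(snp_truth.haplotype_pass_genes)} haplotype-passing genes planted")

    tbl, q_truth = sim.gen_qpcr(seed=SEED)
    tbl.to_csv(OUT / "qpcr_ct.csv", index=False)
    q_truth.to_json(OUT / "qpcr_truth.json")
    print(f"qPCR Ct table: {len(tbl)} wells, planted folds {q_truth.qpcr_folds}")

    profiles, onl_truth = sim.gen_onl(seed=SEED)
    rows = []
    for p in profiles:
        for h, hemi in enumerate(("superior", "inferior")):
            for s in range(9):
                for pos in range(3):
                    rows.append((p.animal_id, p.genotype, hemi, s + 1, pos + 1,
                                 p.measurements[h, s, pos]))
    import pandas as pd
    pd.DataFrame(rows, columns=["animal", "genotype", "hemisphere", "set",
                                "position", "thickness_um"]).to_csv(
        OUT / "onl.csv", index=False)
    onl_truth.to_json(OUT / "onl_truth.json")
    print(f"ONL table: {len(profiles)} animals, planted means "
          f"{onl_truth.onl_genotype_means}")


if __name__ == "__main__":
    main()
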