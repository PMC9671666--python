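#!/usr/bin/env python
"""Generate the synthetic Citrinae cohort every downstream analysis consumes.

Writes a phased VCF of three drift-structured populations plus a near-fixed
outgroup, with planted pop3 -> pop2 introgression tracts (m = 0.15), a
SIFT-like deleterious annotation layer, gene models with heterozygous
deletions, the F1 pseudo-testcross bulk counts, and MITE insertion evidence —
each with its ground truth — under results/cohort/.
"""

import os

import numpy as np
import pandas as pd

from apomixkit import synth

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "cohort")
SEED = 20220614


def main():
    cfg = synth.SynthConfig(seed=SEED, n_pops=3, samples_per_pop=12,
                            n_variants=12_000, deleterious_fraction=0.025,
                            private_fixed={"pop3": 300})
    vt, gm, truth = synth.simulate_structured_genotypes(cfg)
    recipients = [s for s, p in truth.population_labels.items() if p == "pop2"]
    plan = synth.IntrogressionPlan("pop3", recipients, m=0.15, tract_len=1e6)
    gm, truth = synth.plant_introgression_tracts(gm, vt, truth, plan,
                                                 cfg.contig_lengths, seed=SEED + 1)
    vt, truth = synth.attach_deleterious_annotations(
        vt, truth, cfg.deleterious_fraction, cfg.dfe, seed=SEED + 2)

    genes, dels, g_h = synth.simulate_sv_and_genes(
        synth.SvPlan(n_genes=200, hemizygous_fraction=0.1),
        cfg.contig_lengths, gm.samples, seed=SEED + 3)

    qtl = synth.QtlPlan(n_progeny=554, bulk_size=30, depth=60, n_markers=5000)
    phenotypes, bulk_counts, bsa_truth = synth.simulate_f1_bsa(
        qtl, synth.BSA_CONTIGS, seed=SEED + 4)

    rng = np.random.default_rng(SEED + 5)
    ins_truth = pd.DataFrame({
        "sample": gm.samples, "locus": "FhRWP_promoter",
        "genotype": rng.choice(["absent", "het", "hom"], size=len(gm.samples),
                               p=[0.3, 0.6, 0.1])})
    evidence = synth.simulate_insertion_evidence(ins_truth, depth=30,
                                                 error=0.01, seed=SEED + 6)
    seqs = {"fortunella_hap": synth.make_mite_insertion("fortunella", SEED + 7),
            "citrus_hap": synth.make_mite_insertion("citrus", SEED + 8)}

    paths = synth.write_cohort(OUT, vt, gm, truth, cfg.contig_lengths,
                               genes=genes, het_deletions=dels,
                               bulk_counts=bulk_counts,
                               insertion_evidence=evidence,
                               insertion_seqs=seqs)
    n1 = int(phenotypes.sum())
    pd.DataFrame({"n_apomictic": [n1], "n_sexual": [len(phenotypes) - n1],
                  "qtl_chrom": [qtl.chrom], "qtl_pos": [qtl.pos]}).to_csv(
        os.path.join(OUT, "bsa_truth.tsv"), sep="\t", index=False)
    print(f"cohort written to {OUT}:")
    for name, p in paths.items():
        print(f"  {name}")
    print(f"planted introgression: m=0.15 pop3->pop2 ({len(recipients)} samples)")
    print(f"F1 phenotypes {n1}:{len(phenotypes) - n1}; QTL at {qtl.chrom}:{qtl.pos}")


if __name__ == "__main__":
    main()
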