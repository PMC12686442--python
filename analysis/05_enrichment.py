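"""Set-level interpretation of the N/L differential results.

Ranks proteins by log2 fold change, runs permutation GSEA of the planted
substrate list (the synthetic analogue of a literature-curated CMA substrate
list), runs hypergeometric ORA of the called substrates against synthetic
functional categories, and filters pairwise category overlaps at the
enrichment-map Jaccard threshold of 0.25.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cmaflux import (
    RankedList,
    ora,
    permutation_test,
    set_similarity_filter,
    write_gmt,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240907


def main() -> None:
    diff = pd.read_csv(ROOT / "differential_amd.tsv", sep="\t", index_col=0)
    truth = pd.read_csv(ROOT / "sim" / "nl_amd_truth.tsv", sep="\t")
    ranked = RankedList.from_series(diff["log2_fc"].dropna())

    substrate_list = sorted(truth.loc[truth["is_substrate"], "protein_id"])
    res = permutation_test(ranked, substrate_list, n_perm=1000, seed=SEED % 2**31,
                           set_name="planted_substrates")
    print(f"GSEA of planted substrate list: ES = {res['es']:.3f}, "
          f"NES = {res['nes']:.2f}, p = {res['p_value']:.4g} (1000 permutations)")
    pd.DataFrame([res]).to_csv(ROOT / "gsea_substrates.tsv", sep="\t", index=False)

    # synthetic functional categories: one substrate-rich, others random
    rng = np.random.default_rng(SEED % 2**31)
    proteins = list(diff.index)
    sets = {
        "substrate_rich": sorted(
            set(substrate_list[:30]) | set(rng.choice(proteins, 20, replace=False))
        ),
    }
    for k in range(5):
        sets[f"random_{k}"] = sorted(rng.choice(proteins, 40, replace=False))
    write_gmt(sets, ROOT / "synthetic_sets.gmt")

    called = set(pd.read_csv(ROOT / "substrates_amd.tsv", sep="\t")["protein_id"])
    background = set(diff.index[diff["p_value"].notna()])
    res_ora = ora(called & background, background, sets)
    res_ora.to_csv(ROOT / "ora_amd.tsv", sep="\t", index=False)
    print(res_ora[["set", "overlap", "p_value", "q_value"]].round(4).to_string(index=False))

    edges = set_similarity_filter({n: set(m) for n, m in sets.items()}, jaccard_min=0.25)
    edges.to_csv(ROOT / "ora_edges.tsv", sep="\t", index=False)
    print(f"{len(edges)} category pairs pass the Jaccard >= 0.25 edge filter")


if __name__ == "__main__":
    main()
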