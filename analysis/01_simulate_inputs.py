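"""Generate the three synthetic input classes for the downstream analyses.

Writes a motif-planted proteome, a two-group expression matrix with the CMA
network shifted down in the AMD-like group, and two paired control/N-L
proteomics experiments (a healthy-like and an AMD-like condition, the latter
with more planted substrates), all with truth tables, under results/sim/.
"""

from pathlib import Path

import pandas as pd

from cmaflux import (
    CmaNetworkTable,
    ExpressionConfig,
    NLConfig,
    ProteomeConfig,
    make_expression,
    make_nl_experiment,
    make_proteome,
    write_fasta,
)
from cmaflux.simulate import write_truth

SEED = 20240907
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    records, truth = make_proteome(ProteomeConfig(), seed=SEED)
    write_fasta(records, OUT / "proteome.fasta")
    write_truth(truth, OUT / "proteome_truth.tsv")
    print(f"proteome: {len(records)} proteins, "
          f"{(truth['planted_class'] != 'none').mean():.0%} motif-planted")

    network = CmaNetworkTable.default()
    expr, labels, etruth = make_expression(ExpressionConfig(), network, seed=SEED)
    expr.values.rename_axis("gene").to_csv(OUT / "expression.tsv", sep="\t")
    pd.Series(labels, name="group").rename_axis("sample").to_csv(OUT / "groups.tsv", sep="\t")
    write_truth(etruth, OUT / "expression_truth.tsv")
    print(f"expression: {expr.values.shape[0]} genes x {expr.values.shape[1]} samples, "
          f"{int(etruth['in_network'].sum())} network genes shifted")

    for label, frac, seed in (("healthy", 0.08, SEED + 1), ("amd", 0.15, SEED + 2)):
        quant, qtruth, motifs = make_nl_experiment(NLConfig(frac_substrates=frac), seed=seed)
        quant.intensities.rename_axis("protein_id").to_csv(OUT / f"nl_{label}_quant.tsv", sep="\t")
        quant.design.to_csv(OUT / f"nl_{label}_design.tsv", sep="\t")
        pd.Series(motifs, name="has_motif").rename_axis("protein_id").to_csv(
            OUT / f"nl_{label}_motifs.tsv", sep="\t"
        )
        write_truth(qtruth, OUT / f"nl_{label}_truth.tsv")
        print(f"N/L {label}: {quant.intensities.shape[0]} proteins, "
              f"{int(qtruth['is_substrate'].sum())} planted substrates")


if __name__ == "__main__":
    main()
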