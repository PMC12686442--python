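"""Differential N/L analysis and putative-CMA-substrate calling.

For each simulated condition (healthy-like, AMD-like) runs the paired
row-wise test, applies the substrate filter (FC > 1.25, p < 0.01, motif+),
evaluates recovery against planted truth, and quantifies overlap between the
two called sets with the Jaccard index.  Also reproduces the worked example:
sets of 171 and 328 substrates sharing 118 members give Jaccard 0.3097.
"""

import json
from pathlib import Path

import pandas as pd

from cmaflux import call_substrates, overlap, rowwise_test
from cmaflux.differential import read_quant

ROOT = Path(__file__).resolve().parent.parent / "results"


def run_condition(label: str):
    quant = read_quant(
        ROOT / "sim" / f"nl_{label}_quant.tsv",
        ROOT / "sim" / f"nl_{label}_design.tsv",
        scale="log2",
    )
    motifs_df = pd.read_csv(ROOT / "sim" / f"nl_{label}_motifs.tsv", sep="\t")
    motifs = dict(zip(motifs_df["protein_id"], motifs_df["has_motif"].astype(bool)))
    truth = pd.read_csv(ROOT / "sim" / f"nl_{label}_truth.tsv", sep="\t")

    diff = rowwise_test(quant)
    diff.rename_axis("protein_id").to_csv(ROOT / f"differential_{label}.tsv", sep="\t")
    call = call_substrates(diff, motifs, label=label)
    planted = set(truth.loc[truth["is_substrate"], "protein_id"])
    tp = len(call.proteins & planted)
    print(f"{label}: {call.n} called; sensitivity {tp / len(planted):.2f}, "
          f"FDR {(call.n - tp) / max(call.n, 1):.2f} against planted truth")
    _volcano(diff, label)
    return call


def _volcano(diff: pd.DataFrame, label: str) -> None:
    try:
        import numpy as np
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    fig, ax = plt.subplots(figsize=(4, 4))
    sig = (diff["p_value"] < 0.01) & (diff["log2_fc"] > np.log2(1.25))
    ax.scatter(diff["log2_fc"], -np.log10(diff["p_value"]), s=4, c=sig.map({True: "goldenrod", False: "grey"}))
    ax.set_xlabel("log2 FC (N/L - control)")
    ax.set_ylabel("-log10 p")
    ax.set_title(f"{label} N/L differential")
    fig.tight_layout()
    fig.savefig(ROOT / f"volcano_{label}.png", dpi=120)
    plt.close(fig)


def main() -> None:
    healthy = run_condition("healthy")
    amd = run_condition("amd")

    res = overlap(healthy, amd)
    summary = {
        "healthy_called": res.size_a,
        "amd_called": res.size_b,
        "shared": res.intersection,
        "jaccard": round(res.jaccard, 4),
    }
    print(f"overlap between conditions: {summary}")

    shared = [f"S{i}" for i in range(118)]
    worked = overlap(
        shared + [f"H{i}" for i in range(171 - 118)],
        shared + [f"A{i}" for i in range(328 - 118)],
    )
    summary["worked_example_jaccard"] = round(worked.jaccard, 4)
    print(f"worked example (171 vs 328, 118 shared): Jaccard = {worked.jaccard:.4f}")
    (ROOT / "substrate_overlap.json").write_text(json.dumps(summary, indent=2) + "\n")
    for label, call in (("healthy", healthy), ("amd", amd)):
        pd.Series(sorted(call.proteins), name="protein_id").to_csv(
            ROOT / f"substrates_{label}.tsv", sep="\t", index=False
        )


if __name__ == "__main__":
    main()
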