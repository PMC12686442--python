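"""End-to-end orchestration with a reproducibility manifest.

``run_pipeline`` executes the requested stages in dependency order —
simulate -> scan -> score -> substrates -> overlap/enrich/ora — writing
plain-text TSV/JSON outputs plus a manifest recording input checksums,
parameters and seeds, so a rerun with identical config reproduces every
output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import differential, enrichment, io as cio, motifs, score as score_mod, simulate

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "scan", "score", "substrates", "enrich", "ora")


@dataclass
class RunConfig:
    """Validated pipeline configuration (normally loaded from YAML)."""

    out_dir: Path
    seed: int = 0
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        out_dir = Path(raw.pop("out_dir"))
        seed = int(raw.pop("seed", 0))
        stages = {k: (v or {}) for k, v in raw.items()}
        unknown = set(stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")
        cfg = cls(out_dir=out_dir, seed=seed, stages=stages)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name, params in self.stages.items():
            for key, val in params.items():
                if key in ("fasta", "expression", "network", "groups", "quant", "design", "motifs", "gmt", "ranked"):
                    if val is not None and not Path(val).exists():
                        raise FileNotFoundError(f"stage {name}: input {key}={val} does not exist")
        sub = self.stages.get("substrates", {})
        if sub:
            fc_min = float(sub.get("fc_min", 1.25))
            p_max = float(sub.get("p_max", 0.01))
            if fc_min <= 0 or not 0 < p_max <= 1:
                raise ValueError("substrate thresholds out of documented bounds")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute configured stages; return (and write) the run manifest.

    A stage failure halts the run with the failing stage named; outputs of
    completed stages are retained alongside a FAILED marker file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}, "inputs": {}, "outputs": {}}
    state: dict[str, Any] = {}

    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        params = dict(config.stages[stage])
        for key, val in params.items():
            if isinstance(val, str) and Path(val).is_file():
                manifest["inputs"][f"{stage}.{key}"] = _sha256(Path(val))
        try:
            outputs = _STAGE_FUNCS[stage](params, config, state, out)
        except Exception as exc:
            (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = params
        for name, path in outputs.items():
            manifest["outputs"][f"{stage}.{name}"] = {"path": str(path), "sha256": _sha256(path)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _stage_simulate(params, config, state, out) -> dict[str, Path]:
    seed = int(params.get("seed", config.seed))
    nl_cfg = simulate.NLConfig(**params.get("nl", {}))
    quant, truth, motif = simulate.make_nl_experiment(nl_cfg, seed)
    qp, dp, tp, mp = (out / f for f in ("sim_quant.tsv", "sim_design.tsv", "sim_truth.tsv", "sim_motifs.tsv"))
    quant.intensities.to_csv(qp, sep="\t")
    quant.design.to_csv(dp, sep="\t")
    simulate.write_truth(truth, tp)
    pd.Series(motif, name="has_motif").rename_axis("protein_id").to_csv(mp, sep="\t")
    state["quant"] = quant
    state["motif_annotation"] = motif
    return {"quant": qp, "design": dp, "truth": tp, "motifs": mp}


def _stage_scan(params, config, state, out) -> dict[str, Path]:
    rules = motifs.MotifRuleSet.from_yaml(params["rules"]) if params.get("rules") else motifs.DEFAULT_RULES
    records = motifs.read_fasta(params["fasta"])
    hits = motifs.scan_collection(records, rules)
    summary = motifs.summarize_collection(records, rules, params.get("mode", "inclusive"), hits=hits)
    hp, sp = out / "motif_hits.tsv", out / "motif_summary.json"
    motifs.hits_to_frame([h for hl in hits.values() for h in hl]).to_csv(hp, sep="\t", index=False)
    sp.write_text(json.dumps({"counts": summary.counts, "fractions": summary.fractions,
                              "total": summary.total, "mode": summary.mode}, indent=2) + "\n")
    state["motif_annotation"] = {r.id: bool(hits[r.id]) for r in records}
    return {"hits": hp, "summary": sp}


def _stage_score(params, config, state, out) -> dict[str, Path]:
    expr = cio.read_expression(params["expression"], params.get("scale", "log_normalized"))
    network = (
        score_mod.CmaNetworkTable.from_tsv(params["network"])
        if params.get("network")
        else score_mod.CmaNetworkTable.default()
    )
    result = score_mod.compute_cma_score(expr, network)
    sp = out / "cma_scores.tsv"
    result.scores.rename_axis("sample").to_csv(sp, sep="\t")
    outputs = {"scores": sp}
    if params.get("groups"):
        labels = cio.read_group_labels(params["groups"])
        gp = out / "cma_score_groups.json"
        gp.write_text(json.dumps(score_mod.score_groups(result, labels), indent=2) + "\n")
        outputs["groups"] = gp
    state["cma_scores"] = result
    return outputs


def _stage_substrates(params, config, state, out) -> dict[str, Path]:
    if params.get("quant"):
        quant = differential.read_quant(params["quant"], params["design"], params.get("scale", "raw"))
    else:
        quant = state["quant"]  # wired from the simulate stage
    diff = differential.rowwise_test(quant, params.get("test", "auto"))
    if params.get("motifs"):
        ann_df = pd.read_csv(params["motifs"], sep="\t")
        annotation = dict(zip(ann_df.iloc[:, 0].astype(str), ann_df.iloc[:, 1].astype(bool)))
    else:
        annotation = state["motif_annotation"]
    call = differential.call_substrates(
        diff,
        annotation,
        fc_min=float(params.get("fc_min", 1.25)),
        p_max=float(params.get("p_max", 0.01)),
        label=params.get("label", "NL"),
        require_motif=bool(params.get("require_motif", True)),
    )
    dp, cp = out / "differential.tsv", out / "substrates.tsv"
    diff.rename_axis("protein_id").to_csv(dp, sep="\t")
    pd.Series(sorted(call.proteins), name="protein_id").to_csv(cp, sep="\t", index=False)
    state["diff"] = diff
    state["substrates"] = call
    return {"differential": dp, "substrates": cp}


def _stage_enrich(params, config, state, out) -> dict[str, Path]:
    if params.get("ranked"):
        rk = pd.read_csv(params["ranked"], sep="\t", index_col=0).iloc[:, 0]
    else:
        rk = state["diff"]["log2_fc"].dropna()
    ranked = enrichment.RankedList.from_series(rk)
    sets = enrichment.read_gmt(params["gmt"])
    rows = [
        enrichment.permutation_test(
            ranked, members,
            n_perm=int(params.get("n_perm", 1000)),
            seed=int(params.get("seed", config.seed)),
            weight_exponent=float(params.get("weight_exponent", 1.0)),
            set_name=name,
        )
        for name, members in sets.items()
        if set(members) & set(ranked.ids)
    ]
    ep = out / "gsea.tsv"
    pd.DataFrame(rows).to_csv(ep, sep="\t", index=False)
    return {"gsea": ep}


def _stage_ora(params, config, state, out) -> dict[str, Path]:
    if params.get("query"):
        query = set(pd.read_csv(params["query"], sep="\t").iloc[:, 0].astype(str))
        background = set(pd.read_csv(params["background"], sep="\t").iloc[:, 0].astype(str))
    else:
        query = set(state["substrates"].proteins)
        background = set(state["diff"].index[state["diff"]["p_value"].notna()])
    sets = enrichment.read_gmt(params["gmt"])
    res = enrichment.ora(query, background, sets)
    op = out / "ora.tsv"
    res.to_csv(op, sep="\t", index=False)
    if "jaccard_min" in params and not res.empty:
        edges = enrichment.set_similarity_filter(
            {r["set"]: set(sets[r["set"]]) & background for _, r in res.iterrows()},
            float(params["jaccard_min"]),
        )
        jp = out / "ora_edges.tsv"
        edges.to_csv(jp, sep="\t", index=False)
        return {"ora": op, "edges": jp}
    return {"ora": op}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "scan": _stage_scan,
    "score": _stage_score,
    "substrates": _stage_substrates,
    "enrich": _stage_enrich,
    "ora": _stage_ora,
}
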