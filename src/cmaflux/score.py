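"""Per-sample CMA transcriptional activity score.

The score summarizes transcript levels of the CMA machinery — effectors and
positive modulators push the score up, negative modulators push it down, and
LAMP2 (encoding the rate-limiting lysosomal receptor LAMP-2A) carries double
weight.  Pipeline: log2(x+1) for raw counts, per-gene z-score across samples
(population SD), then a weighted directed average

    score_s = sum_g d_g * w_g * z_{g,s} / sum_g w_g

over the network genes present with nonzero variance.  Z-scoring makes genes
commensurable so the weights are meaningful; the population (n-denominator)
SD keeps tiny fixtures deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger(__name__)

ROLES = ("effector", "positive_modulator", "negative_modulator")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a scale flag."""

    values: pd.DataFrame  # genes in rows, samples in columns
    scale: Literal["raw_counts", "log_normalized"] = "log_normalized"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups}")
        if self.scale not in ("raw_counts", "log_normalized"):
            raise ValueError(f"unknown scale flag {self.scale!r}")
        if self.scale == "raw_counts" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()


@dataclass
class CmaNetworkTable:
    """Gene-level roles, signed directions and weight magnitudes.

    Negative modulators must carry direction -1; LAMP2, when present, must
    carry weight 2 and direction +1 (it is the limiting effector).
    """

    table: pd.DataFrame  # columns: role, direction, weight; index: symbol

    def __post_init__(self) -> None:
        t = self.table
        required = {"role", "direction", "weight"}
        if not required.issubset(t.columns):
            raise ValueError(f"network table needs columns {sorted(required)}")
        if t.index.duplicated().any():
            raise ValueError("duplicate gene symbols in network table")
        bad_roles = set(t["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown roles: {sorted(bad_roles)}")
        if not set(t["direction"]).issubset({1, -1}):
            raise ValueError("directions must be +1 or -1")
        if (t["weight"] <= 0).any():
            raise ValueError("weights must be positive")
        neg = t[t["role"] == "negative_modulator"]
        if (neg["direction"] != -1).any():
            raise ValueError("negative modulators must have direction -1")
        if "LAMP2" in t.index:
            row = t.loc["LAMP2"]
            if row["weight"] != 2 or row["direction"] != 1:
                raise ValueError("LAMP2 must have weight 2 and direction +1")

    @property
    def genes(self) -> list[str]:
        return self.table.index.tolist()

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CmaNetworkTable":
        df = df.copy()
        if "symbol" in df.columns:
            df = df.set_index("symbol")
        df["direction"] = df["direction"].astype(int)
        df["weight"] = df["weight"].astype(float)
        return cls(df[["role", "direction", "weight"]])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CmaNetworkTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CmaNetworkTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_frame(pd.DataFrame(raw))

    @classmethod
    def default(cls) -> "CmaNetworkTable":
        """Literature-curated default CMA network (editable config)."""
        with resources.files("cmaflux.data").joinpath("cma_network.tsv").open() as fh:
            return cls.from_frame(pd.read_csv(fh, sep="\t"))


@dataclass
class CmaScoreResult:
    """Per-sample scores plus bookkeeping of which network genes informed them."""

    scores: pd.Series  # index: samples
    genes_used: list[str]
    genes_dropped: dict[str, str]  # symbol -> reason ("absent" | "zero_variance")


def compute_cma_score(expr: ExpressionMatrix, network: CmaNetworkTable) -> CmaScoreResult:
    """Weighted, directed average of per-gene z-scored expression.

    Raw counts are log2(x+1)-transformed first.  Network genes absent from
    the matrix or with zero variance across samples are dropped (logged) and
    the weight normalizer is recomputed over the genes actually used.
    """
    if len(expr.samples) < 2:
        raise ValueError("need at least 2 samples to z-score expression")

    x = expr.values
    if expr.scale == "raw_counts":
        x = np.log2(x + 1.0)

    used: list[str] = []
    dropped: dict[str, str] = {}
    for g in network.genes:
        if g not in x.index:
            dropped[g] = "absent"
        elif float(x.loc[g].std(ddof=0)) == 0.0:
            dropped[g] = "zero_variance"
            logger.warning("network gene %s has zero variance; dropped", g)
        else:
            used.append(g)
    if not used:
        raise ValueError("no informative network genes")

    sub = x.loc[used]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    z = sub.sub(mu, axis=0).div(sd, axis=0)

    t = network.table.loc[used]
    signed_w = (t["direction"] * t["weight"]).to_numpy()
    scores = pd.Series(signed_w @ z.to_numpy() / t["weight"].sum(), index=x.columns, name="cma_score")
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("non-finite CMA scores")
    return CmaScoreResult(scores=scores, genes_used=used, genes_dropped=dropped)


def score_groups(result: CmaScoreResult, labels: Mapping[str, str]) -> dict:
    """Group means +/- s.e.m. and a two-group unpaired Student's t test.

    ``labels`` maps sample id -> group name; every scored sample must be
    labelled.  The t test is only computed for exactly two groups with at
    least two samples each.
    """
    missing = [s for s in result.scores.index if s not in labels]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    groups = pd.Series({s: labels[s] for s in result.scores.index})
    summary = {}
    for name, idx in groups.groupby(groups).groups.items():
        vals = result.scores.loc[idx]
        summary[name] = {
            "n": int(len(vals)),
            "mean": float(vals.mean()),
            "sem": float(vals.sem()) if len(vals) > 1 else float("nan"),
        }
    out: dict = {"groups": summary}
    if len(summary) == 2:
        (na, ga), (nb, gb) = summary.items()
        a = result.scores.loc[groups[groups == na].index].to_numpy()
        b = result.scores.loc[groups[groups == nb].index].to_numpy()
        if len(a) >= 2 and len(b) >= 2:
            t, p = stats.ttest_ind(a, b, equal_var=True)
            out["comparison"] = {
                "group_a": na,
                "group_b": nb,
                "mean_difference": float(a.mean() - b.mean()),
                "t": float(t),
                "p_value": float(p),
            }
    return out
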