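"""Gene-set enrichment statistics.

Two complementary set-level tests used downstream of the differential stage:

* a rank-based enrichment score (the weighted Kolmogorov-Smirnov running-sum
  statistic): walking down a ranked list, the running sum increments by
  |score|^exponent (normalized over in-set members) at set hits and
  decrements by 1/(N - n_set) at misses; the enrichment score (ES) is the
  signed maximum deviation from zero.  Significance comes from gene-set
  (label) permutation with sign-stratified normalization (NES).

* hypergeometric over-representation (ORA) of a query set against a GMT
  gene-set collection, with Benjamini-Hochberg correction across sets.

Also provides the Jaccard similarity edge filter used to sparsify
enrichment-map style networks of result sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class RankedList:
    """Identifiers ordered by a real-valued score, descending.

    Ties keep the input order (stable sort), so fixed fixtures are
    deterministic.
    """

    ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.scores):
            raise ValueError("ids and scores differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ranked list identifiers must be unique")
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.isfinite(self.scores).all():
            raise ValueError("ranking scores must be finite")
        order = np.argsort(-self.scores, kind="stable")
        self.ids = [self.ids[i] for i in order]
        self.scores = self.scores[order]

    @classmethod
    def from_series(cls, s: pd.Series) -> "RankedList":
        return cls(ids=list(s.index), scores=s.to_numpy(dtype=float))

    def __len__(self) -> int:
        return len(self.ids)


def enrichment_score(
    ranked: RankedList, gene_set: Iterable[str], weight_exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES and the full running sum for one gene set.

    Raises on an empty intersection between the set and the ranked list.
    """
    members = set(gene_set)
    hit = np.array([g in members for g in ranked.ids])
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("empty intersection between gene set and ranked list")
    n = len(ranked)
    if n_hit >= n:
        raise ValueError("gene set must be smaller than the ranked list")

    weights = np.abs(ranked.scores) ** weight_exponent
    hit_weights = np.where(hit, weights, 0.0)
    norm = hit_weights.sum()
    if norm == 0:  # all in-set scores are 0 at exponent > 0: fall back to equal steps
        hit_weights = hit.astype(float)
        norm = hit_weights.sum()
    steps = hit_weights / norm - (~hit).astype(float) / (n - n_hit)
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def leading_edge(ranked: RankedList, gene_set: Iterable[str], weight_exponent: float = 1.0) -> list[str]:
    """Set members at or before the running-sum extremum (after it for ES<0)."""
    members = set(gene_set)
    es, running = enrichment_score(ranked, members, weight_exponent)
    peak = int(np.argmax(np.abs(running)))
    if es >= 0:
        span = ranked.ids[: peak + 1]
    else:
        span = ranked.ids[peak + 1 :]
    return [g for g in span if g in members]


def permutation_test(
    ranked: RankedList,
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
    set_name: str = "",
) -> pd.Series:
    """Gene-set permutation p-value and NES for one set.

    Null ES values come from random same-size member sets drawn from the
    ranked list ("permutations based on gene-set size").  NES divides the
    observed ES by the mean |null ES| of matching sign; the empirical p uses
    add-one smoothing, so p >= 1/(n_perm + 1) and is reproducible under a
    fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    members = set(gene_set) & set(ranked.ids)
    es, _ = enrichment_score(ranked, members, weight_exponent)

    rng = np.random.default_rng(seed)
    ids = np.array(ranked.ids)
    null = np.empty(n_perm)
    for i in range(n_perm):
        rand_set = rng.choice(ids, size=len(members), replace=False)
        null[i], _ = enrichment_score(ranked, rand_set, weight_exponent)

    same_sign = null * np.sign(es) > 0
    denom = np.abs(null[same_sign]).mean() if same_sign.any() else np.nan
    nes = es / denom if denom and np.isfinite(denom) else np.nan
    extreme = same_sign & (np.abs(null) >= abs(es))
    p = (1 + int(extreme.sum())) / (n_perm + 1)
    return pd.Series(
        {
            "set": set_name,
            "set_size": len(members),
            "es": es,
            "nes": nes,
            "p_value": p,
            "n_perm": n_perm,
            "leading_edge": ",".join(leading_edge(ranked, members, weight_exponent)),
        }
    )


def ora(
    query: Iterable[str],
    background: Iterable[str],
    collection: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set against a collection.

    Each gene set is intersected with the background; the p-value is the
    upper tail P(X >= overlap) of Hypergeometric(|background|, |set|,
    |query|).  BH adjustment across sets.  The query must be a subset of the
    background.
    """
    query = set(query)
    background = set(background)
    offenders = sorted(query - background)
    if offenders:
        raise ValueError(f"query ids missing from background: {offenders}")

    rows = []
    for name, members in collection.items():
        in_bg = set(members) & background
        if not in_bg:
            continue
        k = len(query & in_bg)
        p = float(stats.hypergeom.sf(k - 1, len(background), len(in_bg), len(query)))
        rows.append(
            {
                "set": name,
                "set_size": len(in_bg),
                "query_size": len(query),
                "overlap": k,
                "p_value": min(p, 1.0),
                "overlap_members": ",".join(sorted(query & in_bg)),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
    return df


def set_similarity_filter(
    result_sets: Mapping[str, Iterable[str]], jaccard_min: float = 0.25
) -> pd.DataFrame:
    """Edges between result sets whose member Jaccard similarity >= threshold.

    Produces an enrichment-map style edge list (set_a, set_b, jaccard) for
    downstream export; visualization is out of scope.
    """
    names = list(result_sets)
    sets = {n: set(result_sets[n]) for n in names}
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            union = sets[a] | sets[b]
            jac = len(sets[a] & sets[b]) / len(union) if union else 0.0
            if jac >= jaccard_min:
                rows.append({"set_a": a, "set_b": b, "jaccard": jac})
    return pd.DataFrame(rows, columns=["set_a", "set_b", "jaccard"])


# ---------------------------------------------------------------------------
# GMT I/O (tab-separated: name, description, members...)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            sets[name] = list(dict.fromkeys(members))
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")
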