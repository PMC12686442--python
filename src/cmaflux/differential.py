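"""Lysosomal-inhibition flux proteomics: differential tests and substrate calls.

Blocking lysosomal proteolysis (NH4Cl + leupeptin, "N/L") makes lysosomal
degradation substrates accumulate.  Given protein x sample intensity
matrices for control and N/L-treated samples, this module computes per-protein
log2 fold changes and p-values (paired-by-donor one-sample t on per-donor
differences when donor ids are available, Welch two-sample t otherwise),
applies the substrate filter — linear fold change > 1.25, raw p < 0.01 and
presence of at least one KFERQ-like motif — and quantifies substrate-set
overlap with the Jaccard index.

Row-wise tests are vectorized over proteins and are cross-checked in the test
suite against scipy's scalar t-tests.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CONDITIONS = ("control", "NL")


@dataclass
class QuantMatrix:
    """Protein x sample intensities with a condition/donor design.

    ``design`` must have one row per sample with columns ``condition``
    (control / NL) and ``donor``.  Intensities are positive where present;
    missing values are NaN.
    """

    intensities: pd.DataFrame  # proteins x samples
    design: pd.DataFrame  # index: sample id; columns: condition, donor
    scale: Literal["raw", "log2"] = "raw"

    def __post_init__(self) -> None:
        if not {"condition"}.issubset(self.design.columns):
            raise ValueError("design needs a 'condition' column")
        bad = set(self.design["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
        missing = set(self.intensities.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples without design rows: {sorted(missing)}")
        vals = self.intensities.to_numpy(dtype=float)
        if self.scale == "raw" and np.nanmin(vals, initial=np.inf) <= 0:
            raise ValueError("raw intensities must be positive where present")

    @property
    def has_donors(self) -> bool:
        return "donor" in self.design.columns and self.design["donor"].notna().all()


@dataclass
class SubstrateCallSet:
    """Proteins passing the putative-CMA-substrate filter for one condition."""

    label: str
    proteins: frozenset[str]
    fc_min: float
    p_max: float
    motif_required: bool = True

    @property
    def n(self) -> int:
        return len(self.proteins)


@dataclass
class OverlapResult:
    """Set arithmetic between two substrate call sets."""

    size_a: int
    size_b: int
    intersection: int
    union: int
    jaccard: float
    unique_to_a: list[str]
    unique_to_b: list[str]
    shared: list[str]


def _log2_and_normalize(quant: QuantMatrix, normalize: bool) -> pd.DataFrame:
    x = quant.intensities.astype(float)
    if quant.scale == "raw":
        x = np.log2(x)
        if normalize:
            # median-center each sample, as in standard label-free pipelines
            x = x.sub(x.median(axis=0, skipna=True), axis=1)
    return x


def rowwise_test(
    quant: QuantMatrix,
    design: Literal["auto", "paired", "unpaired"] = "auto",
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-protein differential test of N/L vs control.

    paired   one-sample t on per-donor (NL - control) log2 differences
             (replicates within a donor/condition are averaged first);
             requires >= 2 complete donor pairs.
    unpaired Welch two-sample t; requires >= 2 quantified values per group.

    Returns a protein-indexed frame with ``log2_fc`` (NL - control), ``t``,
    ``p_value``, group ns and a ``flag`` column ("" for cleanly tested rows,
    otherwise e.g. ``insufficient_n``, ``one_condition_only``,
    ``degenerate_variance``).  No imputation is performed.
    """
    if design == "auto":
        design = "paired" if quant.has_donors else "unpaired"
    if design == "paired" and not quant.has_donors:
        raise ValueError("paired design requested but donor ids are incomplete")

    x = _log2_and_normalize(quant, normalize)
    meta = quant.design.loc[x.columns]
    ctrl_cols = meta.index[meta["condition"] == "control"]
    nl_cols = meta.index[meta["condition"] == "NL"]
    if len(ctrl_cols) == 0 or len(nl_cols) == 0:
        raise ValueError("both control and NL samples are required")

    if design == "paired":
        donors = sorted(meta["donor"].unique())
        diffs = np.full((x.shape[0], len(donors)), np.nan)
        for j, donor in enumerate(donors):
            dc = meta.index[(meta["donor"] == donor) & (meta["condition"] == "control")]
            dn = meta.index[(meta["donor"] == donor) & (meta["condition"] == "NL")]
            if len(dc) == 0 or len(dn) == 0:
                continue
            diffs[:, j] = x[dn].mean(axis=1, skipna=True) - x[dc].mean(axis=1, skipna=True)
        n = np.sum(~np.isnan(diffs), axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(diffs, axis=1)
            sd = np.nanstd(diffs, axis=1, ddof=1)
        df_arr = n - 1.0
        se = sd / np.sqrt(np.maximum(n, 1))
        out = _t_frame(x.index, mean, sd, se, df_arr, n_a=n, n_b=n, min_n=2)
        out["n_pairs"] = n
    else:
        a = x[nl_cols].to_numpy()
        b = x[ctrl_cols].to_numpy()
        na = np.sum(~np.isnan(a), axis=1)
        nb = np.sum(~np.isnan(b), axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ma, mb = np.nanmean(a, axis=1), np.nanmean(b, axis=1)
            va = np.nanvar(a, axis=1, ddof=1)
            vb = np.nanvar(b, axis=1, ddof=1)
        mean = ma - mb
        with np.errstate(divide="ignore", invalid="ignore"):
            se2 = va / na + vb / nb
            se = np.sqrt(se2)
            # Welch-Satterthwaite degrees of freedom
            df_arr = se2**2 / (
                (va / na) ** 2 / np.maximum(na - 1, 1) + (vb / nb) ** 2 / np.maximum(nb - 1, 1)
            )
        sd = np.sqrt(np.where(np.isnan(va), 0, va) + np.where(np.isnan(vb), 0, vb))
        out = _t_frame(x.index, mean, sd, se, df_arr, n_a=nb, n_b=na, min_n=2)
        out = out.rename(columns={"n_a": "n_control", "n_b": "n_NL"})

    # annotate proteins entirely absent in one condition
    present_ctrl = quant.intensities[ctrl_cols].notna().any(axis=1)
    present_nl = quant.intensities[nl_cols].notna().any(axis=1)
    one_cond = (present_ctrl != present_nl) & (present_ctrl | present_nl)
    out.loc[one_cond, "flag"] = "one_condition_only"
    out.loc[one_cond, ["log2_fc", "t", "p_value"]] = np.nan

    # BH q-values over tested proteins, reported alongside raw p
    out["q_value"] = np.nan
    tested = out["p_value"].notna()
    if tested.any():
        out.loc[tested, "q_value"] = multipletests(
            out.loc[tested, "p_value"], method="fdr_bh"
        )[1]
    return out


def _t_frame(index, mean, sd, se, df_arr, n_a, n_b, min_n) -> pd.DataFrame:
    """Assemble t/p columns from vectorized moments, flagging edge cases."""
    mean = np.asarray(mean, dtype=float)
    enough = (np.minimum(n_a, n_b) >= min_n) & np.isfinite(mean)
    t = np.full(mean.shape, np.nan)
    p = np.full(mean.shape, np.nan)
    flag = np.array([""] * len(mean), dtype=object)

    zero_sd = enough & (sd == 0)
    ok = enough & (sd > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t[ok] = mean[ok] / se[ok]
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_arr[ok])

    # degenerate variance: limiting p-value (0 if means differ, 1 otherwise)
    exactly_equal = zero_sd & (mean == 0)
    t[exactly_equal], p[exactly_equal] = 0.0, 1.0
    shifted = zero_sd & (mean != 0)
    t[shifted] = np.where(mean[shifted] > 0, np.inf, -np.inf)
    p[shifted] = 0.0
    flag[zero_sd] = "degenerate_variance"
    flag[~enough] = "insufficient_n"

    return pd.DataFrame(
        {
            "log2_fc": np.where(enough, mean, np.nan),
            "t": t,
            "p_value": p,
            "n_a": n_a,
            "n_b": n_b,
            "flag": flag,
        },
        index=index,
    )


def call_substrates(
    diff: pd.DataFrame,
    motif_annotation: Mapping[str, bool],
    fc_min: float = 1.25,
    p_max: float = 0.01,
    label: str = "",
    require_motif: bool = True,
    two_sided: bool = False,
) -> SubstrateCallSet:
    """Apply the putative-CMA-substrate filter to a differential result.

    A protein is called when its linear fold change exceeds ``fc_min`` in the
    enrichment direction (log2_fc > log2(fc_min); with ``two_sided`` the
    magnitude is used), its raw p-value is below ``p_max``, and — unless
    ``require_motif`` is off — it carries at least one KFERQ-like motif.
    """
    if not (fc_min > 0):
        raise ValueError("fc_min must be > 0")
    if not (0 < p_max <= 1):
        raise ValueError("p_max must lie in (0, 1]")

    missing = [p for p in diff.index if p not in motif_annotation]
    if require_motif and missing:
        logger.warning("%d proteins lack motif annotation; treated as motif-negative", len(missing))

    log2_thresh = math.log2(fc_min)
    fc = diff["log2_fc"]
    passes_fc = fc.abs() > log2_thresh if two_sided else fc > log2_thresh
    passes_p = diff["p_value"] < p_max
    called = []
    for pid in diff.index[(passes_fc & passes_p).fillna(False)]:
        if require_motif and not motif_annotation.get(pid, False):
            continue
        called.append(pid)
    return SubstrateCallSet(
        label=label,
        proteins=frozenset(called),
        fc_min=fc_min,
        p_max=p_max,
        motif_required=require_motif,
    )


def overlap(a: SubstrateCallSet | Iterable[str], b: SubstrateCallSet | Iterable[str]) -> OverlapResult:
    """Exact set overlap between two substrate call sets.

    The Jaccard index of two empty sets is defined as 0 (with a logged
    notice) rather than NaN.
    """
    sa = set(a.proteins if isinstance(a, SubstrateCallSet) else a)
    sb = set(b.proteins if isinstance(b, SubstrateCallSet) else b)
    inter = sa & sb
    union = sa | sb
    if not union:
        logger.info("Jaccard of two empty sets defined as 0")
        jac = 0.0
    else:
        jac = len(inter) / len(union)
    return OverlapResult(
        size_a=len(sa),
        size_b=len(sb),
        intersection=len(inter),
        union=len(union),
        jaccard=jac,
        unique_to_a=sorted(sa - sb),
        unique_to_b=sorted(sb - sa),
        shared=sorted(inter),
    )


# ---------------------------------------------------------------------------
# I/O


def read_quant(
    intensities_path: str | Path,
    design_path: str | Path,
    scale: Literal["raw", "log2"] = "raw",
) -> QuantMatrix:
    """Load a protein x sample table and its sample annotation (TSV/CSV)."""
    sep_i = "," if str(intensities_path).endswith(".csv") else "\t"
    sep_d = "," if str(design_path).endswith(".csv") else "\t"
    intens = pd.read_csv(intensities_path, sep=sep_i, index_col=0)
    design = pd.read_csv(design_path, sep=sep_d).set_index("sample")
    return QuantMatrix(intensities=intens, design=design, scale=scale)
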