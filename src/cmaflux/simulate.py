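"""Synthetic inputs with known ground truth.

Three generators emulate the pipeline's input classes so every stage can be
exercised against planted truth:

* proteomes in which a controlled fraction of sequences carry exactly one
  planted KFERQ-like motif of a known class, on motif-free backgrounds
  obtained by rejection sampling (so background residue composition stays
  realistic);
* expression matrices with a group contrast planted on the CMA-network
  genes (the "AMD-like" group is shifted against each gene's direction, so
  the planted score difference is negative);
* paired control vs lysosomal-inhibitor (N/L) proteomics experiments:
  log-normal intensity noise (Gaussian on the log2 scale), donor random
  offsets shared between a donor's conditions, and a planted set of
  accumulating, motif-bearing substrate proteins.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .differential import QuantMatrix
from .motifs import (
    ACETYL,
    CANONICAL,
    DEFAULT_RULES,
    PHOSPHO,
    WINDOW,
    MotifRuleSet,
    ProteinRecord,
    classify_window,
    protein_classes,
    scan_protein,
)
from .score import CmaNetworkTable, ExpressionMatrix

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class ProteomeConfig:
    """Synthetic proteome: motif-free backgrounds + planted motif fractions."""

    n_proteins: int = 1000
    length_min: int = 60
    length_max: int = 240
    frac_canonical: float = 0.15
    frac_phospho: float = 0.15
    frac_acetyl: float = 0.10
    max_rejections: int = 5000

    def __post_init__(self) -> None:
        fracs = (self.frac_canonical, self.frac_phospho, self.frac_acetyl)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("planted fractions must lie in [0,1] and sum to <= 1")
        if self.n_proteins <= 0 or self.length_min < WINDOW or self.length_max < self.length_min:
            raise ValueError("invalid proteome dimensions")


@dataclass(frozen=True)
class ExpressionConfig:
    """Two-group expression matrix with a planted CMA-network shift.

    ``effect_size`` (log2 units) shifts each network gene by -direction *
    effect_size in the AMD-like group, so the planted group score difference
    (healthy minus AMD-like) is positive.
    """

    n_genes: int = 200
    n_per_group: int = 8
    effect_size: float = 1.0
    noise_sd: float = 0.5
    baseline_low: float = 2.0
    baseline_high: float = 10.0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_per_group <= 0 or self.noise_sd < 0:
            raise ValueError("invalid expression simulation parameters")


@dataclass(frozen=True)
class NLConfig:
    """Paired control vs N/L proteomics with planted accumulating substrates."""

    n_proteins: int = 500
    frac_substrates: float = 0.1
    accumulation_fc: float = 2.0
    noise_sd: float = 0.1
    n_donors: int = 5
    missing_rate: float = 0.0
    donor_sd: float = 0.3
    background_motif_frac: float = 0.45
    baseline_low: float = 20.0
    baseline_high: float = 30.0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_substrates <= 1:
            raise ValueError("frac_substrates must lie in [0,1]")
        if self.accumulation_fc < 1:
            raise ValueError("accumulation FC must be >= 1")
        if self.n_donors < 2:
            raise ValueError("need at least 2 donors")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0,1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of the three generator configs plus the master seed."""

    seed: int = 0
    proteome: ProteomeConfig = field(default_factory=ProteomeConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    nl: NLConfig = field(default_factory=NLConfig)


# ---------------------------------------------------------------------------
# motif-bearing proteomes


def _window_has_motif(seq: str, rules: MotifRuleSet) -> bool:
    anchors = {rules.anchor, rules.acetyl_anchor_mimic}
    for start in range(len(seq) - WINDOW + 1):
        w = seq[start : start + WINDOW]
        if w[0] not in anchors and w[-1] not in anchors:
            continue  # no anchor at either terminus: no rule can fire
        if classify_window(w, rules):
            return True
    return False


def _random_background(rng: np.random.Generator, length: int, rules: MotifRuleSet, cap: int) -> str:
    for _ in range(cap):
        seq = "".join(rng.choice(AMINO_ACIDS, size=length))
        if not _window_has_motif(seq, rules):
            return seq
    raise RuntimeError(
        "rejection sampling failed to produce a motif-free background; try shorter sequences"
    )


def _sample_composition(rng: np.random.Generator, rules: MotifRuleSet, negative_source: str) -> list[str]:
    """Four residues satisfying canonical composition; the acidic slot may be
    filled from ``negative_source`` ('negative' or 'phospho')."""
    n_hydro, n_pos = (2, 1) if rng.random() < 0.5 else (1, 2)
    pool = list(rules.negative if negative_source == "negative" else rules.phospho_mimics)
    residues = (
        list(rng.choice(sorted(rules.hydrophobic), size=n_hydro))
        + list(rng.choice(sorted(rules.positive), size=n_pos))
        + [pool[rng.integers(len(pool))]]
    )
    rng.shuffle(residues)
    return residues


def make_motif(rng: np.random.Generator, motif_class: str, rules: MotifRuleSet = DEFAULT_RULES) -> str:
    """One random pentapeptide of the requested class."""
    left = rng.random() < 0.5
    if motif_class == CANONICAL:
        anchor, core = rules.anchor, _sample_composition(rng, rules, "negative")
    elif motif_class == PHOSPHO:
        anchor, core = rules.anchor, _sample_composition(rng, rules, "phospho")
    elif motif_class == ACETYL:
        anchor, core = rules.acetyl_anchor_mimic, _sample_composition(rng, rules, "negative")
    else:
        raise ValueError(f"cannot plant motif class {motif_class!r}")
    return anchor + "".join(core) if left else "".join(core) + anchor


def make_proteome(
    config: ProteomeConfig,
    seed: int,
    rules: MotifRuleSet = DEFAULT_RULES,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate a proteome with exact planted motif-class fractions.

    Background proteins contain no motif of any class; each planted protein
    receives one inserted pentapeptide of its assigned class at a random
    interior position, re-sampled until the scanned class set equals exactly
    the assigned class (so truth bookkeeping is exact).  Returns the records
    and a truth table (protein_id, planted_class).
    """
    rng = np.random.default_rng(seed)
    n = config.n_proteins
    n_can = round(config.frac_canonical * n)
    n_pho = round(config.frac_phospho * n)
    n_ace = round(config.frac_acetyl * n)
    classes = [CANONICAL] * n_can + [PHOSPHO] * n_pho + [ACETYL] * n_ace
    classes += ["none"] * (n - len(classes))
    order = rng.permutation(n)
    assigned = [classes[i] for i in order]

    records, truth_rows = [], []
    width = len(str(n))
    for i, cls in enumerate(assigned):
        pid = f"SYN{i + 1:0{width}d}"
        length = int(rng.integers(config.length_min, config.length_max + 1))
        for _ in range(config.max_rejections):
            background = _random_background(rng, length, rules, config.max_rejections)
            if cls == "none":
                seq = background
                break
            motif = make_motif(rng, cls, rules)
            pos = int(rng.integers(1, length - 1))
            seq = background[:pos] + motif + background[pos:]
            found = protein_classes(scan_protein(ProteinRecord(pid, seq), rules))
            if found == {cls}:
                break
        else:
            raise RuntimeError(f"could not plant a clean {cls} motif for {pid}")
        records.append(ProteinRecord(pid, seq))
        truth_rows.append({"protein_id": pid, "planted_class": cls})
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# expression matrices


def make_expression(
    config: ExpressionConfig,
    network: CmaNetworkTable,
    seed: int,
) -> tuple[ExpressionMatrix, dict[str, str], pd.DataFrame]:
    """Two-group log-normalized expression with network genes shifted in one group.

    Returns the matrix, sample -> group labels ('healthy' / 'AMD_like') and a
    per-gene truth table with the applied log2 shift.
    """
    rng = np.random.default_rng(seed)
    net_genes = network.genes
    n_fill = max(config.n_genes - len(net_genes), 0)
    genes = net_genes + [f"GENE{i + 1:04d}" for i in range(n_fill)]
    samples = [f"H{i + 1}" for i in range(config.n_per_group)] + [
        f"A{i + 1}" for i in range(config.n_per_group)
    ]
    labels = {s: ("healthy" if s.startswith("H") else "AMD_like") for s in samples}

    baseline = rng.uniform(config.baseline_low, config.baseline_high, size=len(genes))
    vals = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(len(genes), len(samples)))
    df = pd.DataFrame(vals, index=genes, columns=samples)

    shifts = {}
    amd_cols = [s for s in samples if labels[s] == "AMD_like"]
    for g in net_genes:
        d = int(network.table.loc[g, "direction"])
        shift = -d * config.effect_size
        df.loc[g, amd_cols] += shift
        shifts[g] = shift
    truth = pd.DataFrame(
        {
            "gene": genes,
            "in_network": [g in net_genes for g in genes],
            "amd_shift_log2": [shifts.get(g, 0.0) for g in genes],
        }
    )
    return ExpressionMatrix(values=df, scale="log_normalized"), labels, truth


# ---------------------------------------------------------------------------
# paired control / N-L proteomics


def make_nl_experiment(
    config: NLConfig, seed: int
) -> tuple[QuantMatrix, pd.DataFrame, dict[str, bool]]:
    """Paired control vs N/L intensities with planted substrates.

    Control log2 intensity per protein ~ Normal(mu_p, noise_sd) plus a donor
    offset shared by the donor's two conditions; N/L adds
    log2(accumulation_fc) to planted substrates only.  Missing values are
    dropped completely at random at ``missing_rate``.  All planted substrates
    are motif-positive in the companion annotation; background proteins are
    motif-positive at ``background_motif_frac``.  Returns the quantification
    matrix (log2 scale), a truth table, and the motif annotation.
    """
    rng = np.random.default_rng(seed)
    n = config.n_proteins
    width = len(str(n))
    proteins = [f"P{i + 1:0{width}d}" for i in range(n)]
    n_sub = round(config.frac_substrates * n)
    substrate_ids = set(np.array(proteins)[rng.permutation(n)[:n_sub]])

    mu = rng.uniform(config.baseline_low, config.baseline_high, size=n)
    donor_offset = rng.normal(0.0, config.donor_sd, size=config.n_donors)
    log_fc = np.log2(config.accumulation_fc)
    is_sub = np.array([p in substrate_ids for p in proteins])

    cols, design_rows, data = [], [], []
    for d in range(config.n_donors):
        for cond in ("control", "NL"):
            sample = f"D{d + 1}_{cond}"
            vals = mu + donor_offset[d] + rng.normal(0.0, config.noise_sd, size=n)
            if cond == "NL":
                vals = vals + np.where(is_sub, log_fc, 0.0)
            cols.append(sample)
            design_rows.append({"sample": sample, "condition": cond, "donor": f"D{d + 1}"})
            data.append(vals)

    intens = pd.DataFrame(np.column_stack(data), index=proteins, columns=cols)
    if config.missing_rate > 0:
        mask = rng.random(intens.shape) < config.missing_rate
        intens = intens.mask(mask)

    motif = {
        p: True if p in substrate_ids else bool(rng.random() < config.background_motif_frac)
        for p in proteins
    }
    truth = pd.DataFrame(
        {
            "protein_id": proteins,
            "is_substrate": is_sub,
            "has_motif": [motif[p] for p in proteins],
            "planted_log2_fc": np.where(is_sub, log_fc, 0.0),
        }
    )
    design = pd.DataFrame(design_rows).set_index("sample")
    return QuantMatrix(intensities=intens, design=design, scale="log2"), truth, motif


# ---------------------------------------------------------------------------
# truth table round-trip helpers


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
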