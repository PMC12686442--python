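"""KFERQ-like pentapeptide motif scanning and classification.

Chaperone-mediated autophagy (CMA) substrates carry a five-residue targeting
signal recognized by the chaperone HSC70.  The canonical motif is anchored by
a glutamine (Q) at either end of the pentapeptide, with the remaining four
residues drawn from three biochemical classes: one or two hydrophobic
(F/I/L/V), one or two positively charged (K/R), and exactly one negatively
charged (E/D) residue.  Post-translational modifications can create motifs in
otherwise non-qualifying windows: a phosphorylated S/T/Y can stand in for the
acidic residue (phosphorylation-generated), and an acetylated terminal lysine
can mimic the Q anchor (acetylation-generated).

This module classifies every 5-mer window of a protein against a configurable
rule set, scans whole FASTA collections, summarizes motif-class abundance, and
compares abundances between a query collection and a reference proteome with
exact 2x2 tests.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

CANONICAL = "canonical"
PHOSPHO = "phospho_generated"
ACETYL = "acetyl_generated"
PHOSPHO_ACETYL = "phospho_acetyl_generated"

#: priority used for exclusive per-protein class assignment
CLASS_PRIORITY = (CANONICAL, PHOSPHO, ACETYL, PHOSPHO_ACETYL)

WINDOW = 5


class MotifCall(NamedTuple):
    """One classification a 5-mer window admits.

    ``ptm_position`` is 0-based *within the window* (the substituted S/T/Y for
    phosphorylation-generated motifs, the anchor K for acetylation-generated
    ones); ``None`` for canonical.
    """

    motif_class: str
    anchor_terminus: Literal["left", "right"]
    ptm_position: int | None


@dataclass(frozen=True)
class MotifRuleSet:
    """Composition rules defining KFERQ-like motifs.

    The four non-anchor residues must be fully accounted for by the three
    residue classes: ``hydrophobic_range`` of {F,I,L,V}, ``positive_range`` of
    {K,R} and exactly ``negative_count`` of {E,D} (after at most one PTM
    substitution).  The table is configurable so divergent rule dialects can
    be loaded from YAML.
    """

    hydrophobic: frozenset[str] = frozenset("FILV")
    positive: frozenset[str] = frozenset("KR")
    negative: frozenset[str] = frozenset("ED")
    anchor: str = "Q"
    phospho_mimics: frozenset[str] = frozenset("STY")
    acetyl_anchor_mimic: str = "K"
    hydrophobic_range: tuple[int, int] = (1, 2)
    positive_range: tuple[int, int] = (1, 2)
    negative_count: int = 1
    allow_combined_ptm: bool = False

    def __post_init__(self) -> None:
        classes = [self.hydrophobic, self.positive, self.negative]
        for i, a in enumerate(classes):
            for b in classes[i + 1 :]:
                if a & b:
                    raise ValueError(f"residue classes overlap: {sorted(a & b)}")
        if self.anchor in self.hydrophobic | self.positive | self.negative:
            raise ValueError("anchor residue must not belong to a residue class")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MotifRuleSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("hydrophobic", "positive", "negative", "phospho_mimics"):
            if key in raw:
                kwargs[key] = frozenset(raw[key])
        for key in ("anchor", "acetyl_anchor_mimic", "negative_count", "allow_combined_ptm"):
            if key in raw:
                kwargs[key] = raw[key]
        for key in ("hydrophobic_range", "positive_range"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        return cls(**kwargs)


DEFAULT_RULES = MotifRuleSet()


@dataclass(frozen=True)
class ProteinRecord:
    """A protein accession and its amino-acid sequence (upper-case)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class MotifHit:
    """A located motif call on a protein.

    Coordinates are 0-based half-open on the protein sequence;
    ``ptm_position`` is the absolute 0-based index of the modified residue.
    """

    protein_id: str
    start: int
    end: int
    window: str
    motif_class: str
    anchor_terminus: str
    ptm_position: int | None

    def __post_init__(self) -> None:
        if self.end - self.start != WINDOW:
            raise ValueError("motif window must span exactly 5 residues")
        if (self.ptm_position is None) != (self.motif_class == CANONICAL):
            raise ValueError("ptm_position present iff motif class is PTM-generated")


@dataclass
class MotifSummary:
    """Per-class counts/fractions of motif-bearing proteins in a collection."""

    counts: dict[str, int]
    fractions: dict[str, float]
    total: int
    mode: Literal["inclusive", "exclusive"]


def _composition_ok(residues: Sequence[str], rules: MotifRuleSet, extra_negative: int = 0) -> bool:
    """True if the non-anchor residues satisfy canonical composition.

    ``extra_negative`` counts a substituted residue (phospho-mimic) already
    removed from ``residues``.
    """
    counts = Counter(residues)
    h = sum(counts[r] for r in rules.hydrophobic)
    p = sum(counts[r] for r in rules.positive)
    n = sum(counts[r] for r in rules.negative) + extra_negative
    if h + p + n != len(residues) + extra_negative:
        return False  # an unclassed residue remains
    return (
        rules.hydrophobic_range[0] <= h <= rules.hydrophobic_range[1]
        and rules.positive_range[0] <= p <= rules.positive_range[1]
        and n == rules.negative_count
    )


def classify_window(window: str, rules: MotifRuleSet = DEFAULT_RULES) -> set[MotifCall]:
    """Return every motif classification a 5-mer window admits.

    A window already canonical at an anchor is not additionally reported as
    phosphorylation-generated at that same anchor.  Windows containing a
    non-standard letter (X, B, Z, U, O, J, ``*``...) are voided (empty set).
    Exactly one PTM substitution is considered per classification.
    """
    if len(window) != WINDOW:
        raise ValueError(f"window must have length {WINDOW}, got {len(window)}")
    w = window.upper()
    if any(c not in STANDARD_AA for c in w):
        logger.info("window %r contains a non-standard residue; voided", window)
        return set()

    calls: set[MotifCall] = set()
    for terminus, anchor_idx in (("left", 0), ("right", WINDOW - 1)):
        rest_idx = [i for i in range(WINDOW) if i != anchor_idx]
        rest = [w[i] for i in rest_idx]
        anchor_res = w[anchor_idx]
        if anchor_res == rules.anchor:
            if _composition_ok(rest, rules):
                calls.add(MotifCall(CANONICAL, terminus, None))
            else:
                for i in rest_idx:
                    if w[i] not in rules.phospho_mimics:
                        continue
                    others = [w[j] for j in rest_idx if j != i]
                    if _composition_ok(others, rules, extra_negative=1):
                        calls.add(MotifCall(PHOSPHO, terminus, i))
        elif anchor_res == rules.acetyl_anchor_mimic:
            if _composition_ok(rest, rules):
                calls.add(MotifCall(ACETYL, terminus, anchor_idx))
            elif rules.allow_combined_ptm:
                for i in rest_idx:
                    if w[i] not in rules.phospho_mimics:
                        continue
                    others = [w[j] for j in rest_idx if j != i]
                    if _composition_ok(others, rules, extra_negative=1):
                        calls.add(MotifCall(PHOSPHO_ACETYL, terminus, i))
    return calls


def scan_protein(record: ProteinRecord, rules: MotifRuleSet = DEFAULT_RULES) -> list[MotifHit]:
    """All motif hits over every 5-mer window, in ascending start order.

    Overlapping hits are all reported; sequences shorter than 5 residues
    yield an empty list.
    """
    seq = record.sequence
    hits: list[MotifHit] = []
    for start in range(len(seq) - WINDOW + 1):
        window = seq[start : start + WINDOW]
        for call in sorted(classify_window(window, rules)):
            ptm = None if call.ptm_position is None else start + call.ptm_position
            hits.append(
                MotifHit(
                    protein_id=record.id,
                    start=start,
                    end=start + WINDOW,
                    window=window,
                    motif_class=call.motif_class,
                    anchor_terminus=call.anchor_terminus,
                    ptm_position=ptm,
                )
            )
    return hits


def scan_collection(
    records: Iterable[ProteinRecord], rules: MotifRuleSet = DEFAULT_RULES
) -> dict[str, list[MotifHit]]:
    """Scan a protein collection; duplicate ids are a collection-level error."""
    out: dict[str, list[MotifHit]] = {}
    for rec in records:
        if rec.id in out:
            raise ValueError(f"duplicate protein id in collection: {rec.id}")
        out[rec.id] = scan_protein(rec, rules)
    return out


def protein_classes(hits: Sequence[MotifHit]) -> set[str]:
    return {h.motif_class for h in hits}


def summarize_collection(
    records: Sequence[ProteinRecord],
    rules: MotifRuleSet = DEFAULT_RULES,
    mode: Literal["inclusive", "exclusive"] = "inclusive",
    hits: dict[str, list[MotifHit]] | None = None,
) -> MotifSummary:
    """Per-class counts and fractions of motif-bearing proteins.

    ``inclusive`` counts a protein in every class it contains; ``exclusive``
    assigns each protein to the single highest-priority class it contains
    (canonical > phosphorylation- > acetylation-generated).  Pass ``hits``
    to reuse a previous :func:`scan_collection` result.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot summarize an empty collection")
    if mode not in ("inclusive", "exclusive"):
        raise ValueError(f"unknown mode {mode!r}")
    if hits is None:
        hits = scan_collection(records, rules)

    classes = [c for c in CLASS_PRIORITY if c != PHOSPHO_ACETYL or rules.allow_combined_ptm]
    counts = dict.fromkeys(classes, 0)
    for rec in records:
        present = protein_classes(hits[rec.id])
        if mode == "inclusive":
            for cls in classes:
                if cls in present:
                    counts[cls] += 1
        else:
            for cls in classes:
                if cls in present:
                    counts[cls] += 1
                    break
    total = len(records)
    fractions = {c: counts[c] / total for c in classes}
    return MotifSummary(counts=counts, fractions=fractions, total=total, mode=mode)


def compare_to_reference(
    query: MotifSummary, reference: MotifSummary
) -> pd.DataFrame:
    """Per-class motif abundance in a query collection vs a reference proteome.

    Each class forms a 2x2 contingency (contains / not-contains x query /
    reference) analyzed with Fisher's exact test (two-sided); p-values are
    Benjamini-Hochberg adjusted across classes.  When a zero cell occurs the
    conditional odds ratio is degenerate, so a Haldane-Anscombe corrected
    (add 0.5 to each cell) sample odds ratio is reported with a note.
    """
    if set(query.counts) != set(reference.counts):
        raise ValueError("query and reference summaries cover different class sets")
    if query.total <= 0 or reference.total <= 0:
        raise ValueError("summaries must have positive protein totals")

    rows = []
    for cls in query.counts:
        a, b = query.counts[cls], query.total - query.counts[cls]
        c, d = reference.counts[cls], reference.total - reference.counts[cls]
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        note = ""
        if 0 in (a, b, c, d):
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            note = "haldane_continuity"
        rows.append(
            {
                "motif_class": cls,
                "query_with": a,
                "query_total": query.total,
                "reference_with": c,
                "reference_total": reference.total,
                "odds_ratio": odds,
                "p_value": p,
                "note": note,
            }
        )
    df = pd.DataFrame(rows).set_index("motif_class")
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record protein FASTA; the description after the first
    whitespace is ignored for ids."""
    return [ProteinRecord(id=rec.id, sequence=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    """Tabulate hits with 1-based closed coordinates for reporting."""
    rows = [
        {
            "protein_id": h.protein_id,
            "start_1based": h.start + 1,
            "end_1based": h.end,
            "window": h.window,
            "class": h.motif_class,
            "anchor": h.anchor_terminus,
            "ptm_position_1based": "" if h.ptm_position is None else h.ptm_position + 1,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "start_1based",
            "end_1based",
            "window",
            "class",
            "anchor",
            "ptm_position_1based",
        ],
    )
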