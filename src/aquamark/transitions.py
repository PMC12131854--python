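"""In-silico tryptic digestion and MRM transition-list design.

Builds a dynamic-MRM-ready transition list from a protein FASTA: tryptic
digestion with zero missed cleavages, peptide eligibility filtering
(length 6-30, no Cys/Met, unique to one protein, >= 2 peptides per
protein), and selection of three singly charged y/b product ions per
peptide whose m/z exceeds the doubly charged precursor m/z.  The
precursor-exceeding rule guards against co-isolated contaminant ions:
only fragments of a multiply charged precursor can appear above the
precursor's own m/z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from pyteomics import mass as _pt_mass

logger = logging.getLogger(__name__)

PROTON = 1.007276
WATER = 18.010565

#: Monoisotopic residue masses for the 20 canonical amino acids.
RESIDUE_MASS: dict[str, float] = {
    aa: _pt_mass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

TRANSITION_COLUMNS = [
    "protein",
    "peptide",
    "precursor_mz",
    "precursor_charge",
    "ion",
    "fragment_index",
    "product_mz",
    "product_charge",
]


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with parent-protein bookkeeping."""

    sequence: str
    parent_ids: frozenset[str]
    start_pos: int = 0

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)

    @property
    def is_canonical(self) -> bool:
        return all(r in RESIDUE_MASS for r in self.sequence)


@dataclass(frozen=True)
class TransitionRecord:
    """One MRM transition: precursor -> product ion."""

    protein_id: str
    peptide_sequence: str
    precursor_charge: int
    precursor_mz: float
    ion_type: str  # "y" or "b"
    fragment_index: int
    product_charge: int
    product_mz: float


def peptide_mz(sequence: str, charge: int) -> float:
    """Monoisotopic m/z of the intact peptide at ``charge``.

    (sum of residue masses + H2O + charge * proton) / charge.
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    try:
        residue_sum = sum(RESIDUE_MASS[r] for r in sequence)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {sequence!r}") from exc
    return (residue_sum + WATER + charge * PROTON) / charge


def fragment_mz(sequence: str, ion_type: str, index: int, charge: int = 1) -> float:
    """Monoisotopic m/z of the b- or y-ion at ``index`` (1-based).

    b_i covers the first ``index`` residues (no water); y_i covers the
    last ``index`` residues plus water.
    """
    if not 1 <= index < len(sequence):
        raise ValueError(
            f"fragment index {index} out of range for peptide of length {len(sequence)}"
        )
    if ion_type == "b":
        piece = sequence[:index]
        extra = 0.0
    elif ion_type == "y":
        piece = sequence[-index:]
        extra = WATER
    else:
        raise ValueError(f"ion_type must be 'y' or 'b', got {ion_type!r}")
    try:
        residue_sum = sum(RESIDUE_MASS[r] for r in piece)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in {sequence!r}") from exc
    return (residue_sum + extra + charge * PROTON) / charge


def digest(
    fasta_records: Iterable[tuple[str, str]],
    *,
    proline_rule: bool = True,
) -> list[Peptide]:
    """Tryptic digestion with zero missed cleavages.

    Cleaves C-terminal to K or R; with ``proline_rule`` (default) cleavage
    is suppressed when the next residue is P.  Records are ``(protein_id,
    sequence)`` pairs.  Peptides sharing a sequence are merged with the
    union of their parent ids so database-relative uniqueness can be
    checked downstream.  Non-canonical residues do not abort the digest;
    the offending peptide is simply flagged by ``Peptide.is_canonical``.
    """
    by_sequence: dict[str, dict] = {}
    for protein_id, sequence in fasta_records:
        if not sequence:
            raise ValueError(f"empty sequence for protein {protein_id!r}")
        sequence = sequence.upper()
        start = 0
        for i, residue in enumerate(sequence):
            at_end = i == len(sequence) - 1
            cleave = residue in "KR" and not (
                proline_rule and not at_end and sequence[i + 1] == "P"
            )
            if cleave or at_end:
                frag = sequence[start : i + 1]
                entry = by_sequence.setdefault(
                    frag, {"parents": set(), "start": start}
                )
                entry["parents"].add(protein_id)
                start = i + 1
    return [
        Peptide(seq, frozenset(entry["parents"]), entry["start"])
        for seq, entry in by_sequence.items()
    ]


def filter_peptides(
    peptides: Sequence[Peptide],
    *,
    min_length: int = 6,
    max_length: int = 30,
    forbidden_residues: str = "CM",
    min_peptides_per_protein: int = 2,
) -> list[Peptide]:
    """Apply MRM eligibility rules to a digested peptide set.

    A peptide survives if its length is in ``[min_length, max_length]``,
    it contains none of the ``forbidden_residues`` (Cys/Met are excluded
    to avoid variable oxidation/alkylation states), and it maps to
    exactly one protein of the supplied database.  Proteins left with
    fewer than ``min_peptides_per_protein`` survivors are dropped
    entirely, since a protein must be represented by two or more unique
    peptides to be quantifiable.
    """
    if not peptides:
        raise ValueError("empty database: no peptides to filter")
    survivors = []
    for pep in peptides:
        if not pep.is_canonical:
            continue
        if not min_length <= len(pep.sequence) <= max_length:
            continue
        if any(r in forbidden_residues for r in pep.sequence):
            continue
        if len(pep.parent_ids) != 1:
            continue
        survivors.append(pep)
    counts: dict[str, int] = {}
    for pep in survivors:
        (parent,) = pep.parent_ids
        counts[parent] = counts.get(parent, 0) + 1
    kept = [pep for pep in survivors if counts[next(iter(pep.parent_ids))] >= min_peptides_per_protein]
    dropped = {p for p, c in counts.items() if c < min_peptides_per_protein}
    for protein in sorted(dropped):
        logger.info(
            "protein %s dropped: only %d eligible unique peptide(s)",
            protein,
            counts[protein],
        )
    return kept


def select_transitions(
    peptide: Peptide,
    *,
    precursor_charge: int = 2,
    product_charge: int = 1,
    n_transitions: int = 3,
) -> list[TransitionRecord]:
    """Pick the top product ions for one eligible peptide.

    Candidates are the singly charged y- and b-ions; only those with
    product m/z strictly greater than the precursor m/z survive.  The
    survivors are ranked by fragment index descending (longer fragments
    carry more sequence specificity), y before b at equal index, and the
    top ``n_transitions`` are returned.  Fewer survivors than requested
    means the peptide is unusable and an empty list is returned.
    """
    (protein_id,) = peptide.parent_ids if len(peptide.parent_ids) == 1 else (
        sorted(peptide.parent_ids)[0],
    )
    seq = peptide.sequence
    prec_mz = peptide_mz(seq, precursor_charge)
    candidates = []
    for index in range(1, len(seq)):
        for ion in ("y", "b"):
            pmz = fragment_mz(seq, ion, index, product_charge)
            if pmz > prec_mz:
                candidates.append(
                    TransitionRecord(
                        protein_id=protein_id,
                        peptide_sequence=seq,
                        precursor_charge=precursor_charge,
                        precursor_mz=prec_mz,
                        ion_type=ion,
                        fragment_index=index,
                        product_charge=product_charge,
                        product_mz=pmz,
                    )
                )
    candidates.sort(key=lambda t: (-t.fragment_index, t.ion_type != "y"))
    if len(candidates) < n_transitions:
        logger.info(
            "peptide %s dropped: only %d product ion(s) above precursor m/z",
            seq,
            len(candidates),
        )
        return []
    return candidates[:n_transitions]


def design_transitions(
    fasta_records: Iterable[tuple[str, str]],
    *,
    precursor_charge: int = 2,
    proline_rule: bool = True,
    min_peptides_per_protein: int = 2,
) -> list[TransitionRecord]:
    """Full design pipeline: digest, filter, select, re-check protein support."""
    peptides = digest(fasta_records, proline_rule=proline_rule)
    eligible = filter_peptides(
        peptides, min_peptides_per_protein=min_peptides_per_protein
    )
    by_protein: dict[str, list[list[TransitionRecord]]] = {}
    for pep in eligible:
        recs = select_transitions(pep, precursor_charge=precursor_charge)
        if recs:
            by_protein.setdefault(recs[0].protein_id, []).append(recs)
    records: list[TransitionRecord] = []
    for protein in sorted(by_protein):
        peptide_sets = by_protein[protein]
        if len(peptide_sets) < min_peptides_per_protein:
            logger.info(
                "protein %s dropped after transition selection: %d peptide(s) usable",
                protein,
                len(peptide_sets),
            )
            continue
        for recs in sorted(peptide_sets, key=lambda r: r[0].peptide_sequence):
            records.extend(recs)
    return records


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA; the first whitespace token of the header is the id."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def transitions_to_frame(records: Sequence[TransitionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein": r.protein_id,
                "peptide": r.peptide_sequence,
                "precursor_mz": r.precursor_mz,
                "precursor_charge": r.precursor_charge,
                "ion": r.ion_type,
                "fragment_index": r.fragment_index,
                "product_mz": r.product_mz,
                "product_charge": r.product_charge,
            }
            for r in records
        ],
        columns=TRANSITION_COLUMNS,
    )


def write_transition_list(records: Sequence[TransitionRecord], path: str | Path) -> None:
    """Write the transition list as CSV (dynamic-MRM import layout)."""
    transitions_to_frame(records).to_csv(path, index=False)


def read_transition_list(path: str | Path) -> list[TransitionRecord]:
    df = pd.read_csv(path)
    return [
        TransitionRecord(
            protein_id=row.protein,
            peptide_sequence=row.peptide,
            precursor_charge=int(row.precursor_charge),
            precursor_mz=float(row.precursor_mz),
            ion_type=row.ion,
            fragment_index=int(row.fragment_index),
            product_charge=int(row.product_charge),
            product_mz=float(row.product_mz),
        )
        for row in df.itertuples()
    ]


#: The four E. coli beta-galactosidase spike-in peptides added to every
#: sample before digestion as a loading/QC standard.
SPIKEIN_PEPTIDES = (
    "APLDNDIGVSEATR",
    "VDEDQPFPAVPK",
    "IDPNAWVER",
    "VNWLGLGPQENYPDR",
)
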