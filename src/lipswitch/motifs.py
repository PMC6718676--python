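"""Motif filtering and charge analysis for ORP/Osh-family sequences.

The family carries a literal signature motif (``EQTSHHPP``, the Prosite
PS01013 pattern core) and the PS-recognizing lid pattern ``LPTFILE``; family
curation reduces to requiring such literal motifs.  ``x`` in a motif matches
any single residue.  Net peptide charge is counted at pH ~7: K and R +1, D
and E -1, histidine neutral by default, termini ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "AMINO_ACIDS",
    "SIGNATURE_MOTIF",
    "PS_MOTIF",
    "SequenceRecord",
    "MutationSpec",
    "MUTATION_PRESETS",
    "scan_motif",
    "filter_by_motifs",
    "net_charge",
    "apply_mutations",
    "read_fasta",
    "write_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: ORP/Osh family signature (literal core of Prosite pattern PS01013).
SIGNATURE_MOTIF = "EQTSHHPP"
#: PS-recognizing pattern of the Osh6/Osh7-type lid.
PS_MOTIF = "LPTFILE"


@dataclass
class SequenceRecord:
    """A protein sequence over the 20-letter amino-acid alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"invalid residues in {self.id}: {sorted(bad)}")


@dataclass
class MutationSpec:
    """Point substitutions as (1-based position, from_aa, to_aa) triples."""

    mutations: list = field(default_factory=list)
    name: str = ""


#: Lid-charge presets: a single lid point mutation and the two
#: anion-neutralizing D/E-motif mutants (four and seven substitutions).
MUTATION_PRESETS = {
    "L69D": MutationSpec([(69, "L", "D")], name="L69D"),
    "4A": MutationSpec(
        [(38, "D", "A"), (39, "D", "A"), (41, "D", "A"), (42, "E", "A")],
        name="4A",
    ),
    "5A2G": MutationSpec(
        [
            (38, "D", "A"),
            (39, "D", "A"),
            (41, "D", "A"),
            (42, "E", "A"),
            (43, "D", "G"),
            (44, "D", "G"),
            (45, "E", "A"),
        ],
        name="5A2G",
    ),
}


def scan_motif(record: SequenceRecord | str, motif: str) -> list[int]:
    """All (possibly overlapping) 1-based start positions of a literal motif.

    ``x`` in the motif matches any single residue.
    """
    seq = record.sequence if isinstance(record, SequenceRecord) else record
    if not motif:
        raise ValueError("motif must be non-empty")
    bad = set(motif) - set(AMINO_ACIDS) - {"x"}
    if bad:
        raise ValueError(f"invalid motif characters: {sorted(bad)}")
    m = len(motif)
    hits = []
    for start in range(len(seq) - m + 1):
        window = seq[start : start + m]
        if all(mc == "x" or mc == wc for mc, wc in zip(motif, window)):
            hits.append(start + 1)
    return hits


def filter_by_motifs(
    records: list[SequenceRecord],
    require: list[str] | None = None,
    reject_if_missing: list[str] | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Two-stage motif filter.

    A record is first rejected when it lacks any motif in
    ``reject_if_missing`` (family-signature stage), then rejected when it
    lacks any motif in ``require`` (selection stage).  Returns the retained
    records and a per-record report with the decisive reason.
    """
    require = list(require or [])
    reject_if_missing = list(reject_if_missing or [])
    retained: list[SequenceRecord] = []
    rows = []
    for rec in records:
        reason = "retained"
        for motif in reject_if_missing:
            if not scan_motif(rec, motif):
                reason = f"missing signature {motif}"
                break
        else:
            for motif in require:
                if not scan_motif(rec, motif):
                    reason = f"lacks required {motif}"
                    break
        if reason == "retained":
            retained.append(rec)
        rows.append((rec.id, reason))
    report = pd.DataFrame(rows, columns=["id", "status"])
    return retained, report


def net_charge(
    sequence: SequenceRecord | str,
    residue_range: tuple[int, int] | None = None,
    histidine_charge: int = 0,
) -> int:
    """Net charge (#K + #R) − (#D + #E) of a sequence or 1-based inclusive range.

    Histidine counts as ``histidine_charge`` (neutral by default, pH ~7);
    termini are ignored.
    """
    seq = sequence.sequence if isinstance(sequence, SequenceRecord) else sequence
    if residue_range is not None:
        lo, hi = residue_range
        if not 1 <= lo <= hi <= len(seq):
            raise ValueError(
                f"range {residue_range} out of bounds for length {len(seq)}"
            )
        seq = seq[lo - 1 : hi]
    return (
        seq.count("K")
        + seq.count("R")
        - seq.count("D")
        - seq.count("E")
        + histidine_charge * seq.count("H")
    )


def apply_mutations(
    record: SequenceRecord, spec: MutationSpec
) -> tuple[SequenceRecord, int]:
    """Apply point substitutions; returns the mutant and the charge change.

    Every substitution is guarded: the residue found at the 1-based position
    must equal ``from_aa``, which catches numbering drift between the spec
    and the supplied sequence.
    """
    seq = list(record.sequence)
    for pos, from_aa, to_aa in spec.mutations:
        if not 1 <= pos <= len(seq):
            raise ValueError(f"position {pos} outside sequence of length {len(seq)}")
        if seq[pos - 1] != from_aa:
            raise ValueError(
                f"expected {from_aa} at position {pos}, found {seq[pos - 1]}"
            )
        seq[pos - 1] = to_aa
    mutated = SequenceRecord(
        id=f"{record.id}_{spec.name}" if spec.name else record.id,
        sequence="".join(seq),
    )
    delta = net_charge(mutated) - net_charge(record)
    return mutated, delta


def read_fasta(path) -> list[SequenceRecord]:
    return [
        SequenceRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: list[SequenceRecord], path) -> None:
    SeqIO.write(
        [
            _BioSeqRecord(Seq(rec.sequence), id=rec.id, description="")
            for rec in records
        ],
        str(path),
        "fasta",
    )


def positions_array(hits: list[int]) -> np.ndarray:
    return np.asarray(hits, dtype=int)
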