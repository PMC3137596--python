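"""Protein and site I/O: FASTA reading, window extraction, dataset assembly.

The unit of prediction is a single cysteine residue, represented by the
``2n+1``-mer sequence window centered on it.  Positions past either terminus
of the protein are filled with the pad symbol ``'-'`` so every window has the
same length regardless of where the cysteine sits.  A :class:`SiteDataset`
holds the positive windows (experimentally modified cysteines) together with
the negative windows (every other cysteine on the same proteins).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

#: The 20 standard amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Terminal pad symbol — the 21st alphabet symbol used beyond sequence ends.
PAD = "-"
#: Placeholder for unknown / non-standard residues; encodes as all-zero.
UNKNOWN = "X"
#: Full 21-symbol alphabet used by positional encoders.
ALPHABET = AMINO_ACIDS + PAD

_NONSTANDARD = str.maketrans({c: UNKNOWN for c in "BJOUZ"})

POSITIVE = "positive"
NEGATIVE = "negative"


class SequenceIOError(ValueError):
    """Raised for malformed sequence or annotation inputs."""


@dataclass
class ProteinRecord:
    """A protein sequence with an optional per-residue relative ASA track.

    Parameters
    ----------
    id : str
        Accession (first whitespace-delimited token of the FASTA header).
    sequence : str
        Upper-case amino-acid string; non-standard residues (B, J, O, U, Z)
        are mapped to ``'X'``.
    asa : list of float, optional
        Per-residue relative accessible surface area in percent (0-100),
        same length as ``sequence``.
    """

    id: str
    sequence: str
    asa: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceIOError(f"protein {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper().translate(_NONSTANDARD)
        if self.asa is not None:
            if len(self.asa) != len(self.sequence):
                raise SequenceIOError(
                    f"protein {self.id!r}: ASA length {len(self.asa)} != "
                    f"sequence length {len(self.sequence)}"
                )
            if any(not (0.0 <= v <= 100.0) for v in self.asa):
                raise SequenceIOError(
                    f"protein {self.id!r}: ASA values must lie in [0, 100]"
                )

    def cysteine_positions(self) -> list[int]:
        """1-based positions of every cysteine in the sequence."""
        return [i + 1 for i, c in enumerate(self.sequence) if c == "C"]


@dataclass(frozen=True)
class SiteAnnotation:
    """One labelled cysteine site: ``protein_id``, 1-based ``position``."""

    protein_id: str
    position: int
    label: str = POSITIVE

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise SequenceIOError(f"unknown label {self.label!r}")
        if self.position < 1:
            raise SequenceIOError(
                f"{self.protein_id}:{self.position}: positions are 1-based"
            )


@dataclass
class SequenceWindow:
    """A ``2n+1``-mer fragment centered on a cysteine.

    ``residues[center_index] == 'C'`` always holds; pad symbols appear only
    contiguously at the ends.  ``asa``, when present, is normalised to
    [0, 1] with pad positions set to 0.
    """

    residues: str
    center_index: int
    source: tuple[str, int]
    label: str = POSITIVE
    asa: list[float] | None = None

    def __post_init__(self) -> None:
        w = len(self.residues)
        if w % 2 != 1 or self.center_index != w // 2:
            raise SequenceIOError("window length must be odd and centered")
        if self.residues[self.center_index] != "C":
            raise SequenceIOError(
                f"window from {self.source}: center residue is "
                f"{self.residues[self.center_index]!r}, expected 'C'"
            )

    @property
    def n(self) -> int:
        """Half-window size."""
        return self.center_index

    def residue_at(self, offset: int) -> str:
        """Residue at signed offset relative to the center (offset 0 = 'C')."""
        return self.residues[self.center_index + offset]


@dataclass
class SiteDataset:
    """Proteins plus their positive / negative site windows."""

    proteins: dict[str, ProteinRecord]
    positives: list[SequenceWindow] = field(default_factory=list)
    negatives: list[SequenceWindow] = field(default_factory=list)

    @property
    def n(self) -> int:
        for w in self.positives + self.negatives:
            return w.n
        raise SequenceIOError("empty dataset has no window size")

    def validate(self) -> None:
        seen = set()
        for w in self.positives:
            seen.add(w.source)
        for w in self.negatives:
            if w.source in seen:
                raise SequenceIOError(
                    f"site {w.source} appears in both classes"
                )
        for w in self.positives + self.negatives:
            if w.source[0] not in self.proteins:
                raise SequenceIOError(f"window source {w.source} unknown")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    Record ids are the first whitespace-delimited header token; sequences are
    upper-cased.  An entry with a header but no sequence is a parse error.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise SequenceIOError(
                f"{path}: record {rec.id!r} has a header but no sequence"
            )
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def read_annotations(path: str | Path) -> list[SiteAnnotation]:
    """Read a site-annotation TSV: ``protein_id<TAB>position[<TAB>label]``.

    A missing label column means every row is a positive site (negatives are
    then derived from the remaining cysteines by :func:`build_dataset`).
    Lines starting with ``#`` are comments.
    """
    annos = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SequenceIOError(
                    f"{path}:{lineno}: expected protein_id<TAB>position"
                )
            try:
                pos = int(parts[1])
            except ValueError as exc:
                raise SequenceIOError(
                    f"{path}:{lineno}: position {parts[1]!r} is not an integer"
                ) from exc
            label = parts[2] if len(parts) > 2 and parts[2] else POSITIVE
            annos.append(SiteAnnotation(parts[0], pos, label))
    return annos


def write_annotations(
    annos: Iterable[SiteAnnotation], path: str | Path, with_label: bool = True
) -> None:
    with open(path, "w") as fh:
        for a in annos:
            if with_label:
                fh.write(f"{a.protein_id}\t{a.position}\t{a.label}\n")
            else:
                fh.write(f"{a.protein_id}\t{a.position}\n")


def read_asa(
    path: str | Path, proteins: Sequence[ProteinRecord]
) -> list[ProteinRecord]:
    """Attach per-residue ASA values from a TSV of
    ``protein_id<TAB>position<TAB>asa_percent`` rows.

    Every residue of a protein that appears in the file must be covered.
    Returns the same records, mutated in place.
    """
    by_id = {p.id: p for p in proteins}
    values: dict[str, dict[int, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise SequenceIOError(
                    f"{path}:{lineno}: expected protein_id, position, asa"
                )
            pid, pos, val = parts[0], int(parts[1]), float(parts[2])
            values.setdefault(pid, {})[pos] = val
    for pid, vals in values.items():
        if pid not in by_id:
            raise SequenceIOError(f"{path}: unknown protein {pid!r}")
        prot = by_id[pid]
        missing = [
            i for i in range(1, len(prot.sequence) + 1) if i not in vals
        ]
        if missing:
            raise SequenceIOError(
                f"{path}: protein {pid!r} missing ASA for positions "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
        prot.asa = [vals[i] for i in range(1, len(prot.sequence) + 1)]
        ProteinRecord.__post_init__(prot)  # re-validate range/length
    return proteins  # type: ignore[return-value]


def write_asa(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for prot in proteins:
            if prot.asa is None:
                continue
            for i, v in enumerate(prot.asa, 1):
                fh.write(f"{prot.id}\t{i}\t{v:.2f}\n")


def extract_window(
    protein: ProteinRecord, position: int, n: int
) -> SequenceWindow:
    """Extract the ``2n+1``-mer window centered on a cysteine.

    ``position`` is 1-based.  Positions beyond the termini are filled with
    the pad symbol; the matching ASA slots are 0.  ASA values are rescaled
    from percent to [0, 1].
    """
    if not 4 <= n <= 10:
        warnings.warn(
            f"half-window n={n} is outside the usual 4..10 range",
            stacklevel=2,
        )
    L = len(protein.sequence)
    if not 1 <= position <= L:
        raise SequenceIOError(
            f"{protein.id}:{position}: position out of bounds (1..{L})"
        )
    if protein.sequence[position - 1] != "C":
        raise SequenceIOError(
            f"{protein.id}:{position}: residue is "
            f"{protein.sequence[position - 1]!r}, expected cysteine"
        )
    lo = position - 1 - n
    hi = position - 1 + n + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - L)
    core = protein.sequence[max(lo, 0) : min(hi, L)]
    residues = PAD * left_pad + core + PAD * right_pad
    asa = None
    if protein.asa is not None:
        core_asa = [v / 100.0 for v in protein.asa[max(lo, 0) : min(hi, L)]]
        asa = [0.0] * left_pad + core_asa + [0.0] * right_pad
    return SequenceWindow(
        residues=residues,
        center_index=n,
        source=(protein.id, position),
        asa=asa,
    )


def build_dataset(
    proteins: Sequence[ProteinRecord],
    annotations: Sequence[SiteAnnotation],
    n: int = 10,
) -> SiteDataset:
    """Assemble a :class:`SiteDataset` from proteins and site annotations.

    When annotations carry only positive labels, the negative class is every
    *other* cysteine on the annotated proteins — so for each protein the
    positive plus negative windows exhaust its cysteines.  Explicit negative
    labels switch off the auto-derivation and use exactly the given sites.
    """
    by_id = {p.id: p for p in proteins}
    unknown = sorted({a.protein_id for a in annotations} - set(by_id))
    if unknown:
        raise SequenceIOError(
            f"annotations reference unknown proteins: {', '.join(unknown)}"
        )
    has_explicit_neg = any(a.label == NEGATIVE for a in annotations)
    positives: list[SequenceWindow] = []
    negatives: list[SequenceWindow] = []
    pos_sites: set[tuple[str, int]] = set()
    annotated_proteins: list[str] = []
    seen_prot = set()
    for a in annotations:
        if a.protein_id not in seen_prot:
            seen_prot.add(a.protein_id)
            annotated_proteins.append(a.protein_id)
        w = extract_window(by_id[a.protein_id], a.position, n)
        w.label = a.label
        if a.label == POSITIVE:
            positives.append(w)
            pos_sites.add((a.protein_id, a.position))
        else:
            negatives.append(w)
    if not has_explicit_neg:
        for pid in annotated_proteins:
            prot = by_id[pid]
            for pos in prot.cysteine_positions():
                if (pid, pos) in pos_sites:
                    continue
                w = extract_window(prot, pos, n)
                w.label = NEGATIVE
                negatives.append(w)
    ds = SiteDataset(proteins=dict(by_id), positives=positives, negatives=negatives)
    ds.validate()
    return ds
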