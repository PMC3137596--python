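"""Homology reduction between training and independent test datasets.

Independent evaluation is only honest if the test set contains no fragments
the model has effectively seen.  Following common PTM-predictor practice, two
proteins sharing more than 30% pairwise identity are treated as homologues;
their site windows are then compared directly, and any test window identical
to a training window of the same label class is dropped from the test set.
The training set is never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from Bio import Align
from Bio.Align import substitution_matrices

from .sequence_io import SequenceWindow, SiteDataset


@dataclass
class HomologyConfig:
    """Thresholds controlling the reduction.

    protein_identity_threshold : float
        Fraction above which two proteins count as homologous (default 0.30).
    fragment_identity_threshold : float
        Fraction of identical window columns required to discard a test
        window (default 1.00, i.e. exact equality of the ``2n+1``-mer).
    """

    protein_identity_threshold: float = 0.30
    fragment_identity_threshold: float = 1.00

    def __post_init__(self) -> None:
        for name in ("protein_identity_threshold", "fragment_identity_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


def _make_aligner() -> Align.PairwiseAligner:
    # BL2SEQ-like defaults: local alignment, BLOSUM62, affine gaps 11/1.
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Local-alignment identity between two sequences.

    Computed as identical residue pairs divided by the number of aligned
    columns (gap columns included) in the optimal local alignment; 0.0 when
    no alignment with positive score exists.  Co-optimal alignments can
    disagree on identity, so the maximum over (a bounded number of) optimal
    alignments is taken, after canonicalising the argument order — the
    result is symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    a, b = sorted((seq_a.upper(), seq_b.upper()))
    # 'X' scores against BLOSUM62's X column; pads never occur in proteins.
    alignments = _ALIGNER.align(a, b)
    best = 0.0
    for k, alignment in enumerate(alignments):
        if k >= 20:  # co-optimal sets are tiny for real sequences
            break
        counts = alignment.counts()
        ncols = counts.identities + counts.mismatches + counts.gaps
        if ncols:
            best = max(best, counts.identities / ncols)
    return best


def _fragment_identity(a: str, b: str) -> float:
    """Columnwise identity of two equal-length window strings (pads count)."""
    if len(a) != len(b):
        raise ValueError("fragments must have equal length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def reduce_homology(
    train: SiteDataset,
    test: SiteDataset,
    cfg: HomologyConfig | None = None,
    identity_fn: Callable[[str, str], float] = pairwise_identity,
) -> tuple[SiteDataset, list[tuple[str, int]]]:
    """Drop test windows homologous to training windows.

    For every (train protein, test protein) pair exceeding the protein
    identity threshold, test windows whose fragment identity to a train
    window of the same label class reaches ``fragment_identity_threshold``
    are removed.  Negatives are filtered the same way as positives.

    Returns the filtered test dataset and the removal report, a list of
    removed ``(protein_id, position)`` sites.  Idempotent: applying the
    reduction twice equals applying it once.
    """
    cfg = cfg or HomologyConfig()
    if train.positives and test.positives and train.n != test.n:
        raise ValueError(
            f"window size mismatch: train n={train.n}, test n={test.n}"
        )
    homologous_test: set[str] = set()
    for tr in train.proteins.values():
        for te in test.proteins.values():
            if te.id in homologous_test:
                continue
            if identity_fn(tr.sequence, te.sequence) > cfg.protein_identity_threshold:
                homologous_test.add(te.id)

    def keep(window: SequenceWindow, train_windows: list[SequenceWindow]) -> bool:
        if window.source[0] not in homologous_test:
            return True
        for tw in train_windows:
            if (
                _fragment_identity(window.residues, tw.residues)
                >= cfg.fragment_identity_threshold
            ):
                return False
        return True

    removed: list[tuple[str, int]] = []
    kept_pos: list[SequenceWindow] = []
    kept_neg: list[SequenceWindow] = []
    for w in test.positives:
        if keep(w, train.positives):
            kept_pos.append(w)
        else:
            removed.append(w.source)
    for w in test.negatives:
        if keep(w, train.negatives):
            kept_neg.append(w)
        else:
            removed.append(w.source)
    filtered = SiteDataset(
        proteins=dict(test.proteins), positives=kept_pos, negatives=kept_neg
    )
    return filtered, removed


def write_removal_report(
    removed: list[tuple[str, int]], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\n")
        for pid, pos in removed:
            fh.write(f"{pid}\t{pos}\n")
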