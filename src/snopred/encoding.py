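"""Feature encodings for sequence windows.

Encoders map a ``SequenceWindow`` to a numeric block; blocks concatenate into
a single :class:`FeatureVector`.  Available blocks:

``AA_20D``
    Per-position one-hot over the 21-symbol alphabet (20 amino acids + pad);
    ``'X'`` encodes as all-zero.  Length ``21 * (2n+1)``.
``AA_PWM``
    Per-position relative frequency of the observed symbol under a
    positional weight matrix built from positive training windows.
    Length ``2n+1``.
``AAC``
    Amino-acid composition of the window, pads and ``'X'`` excluded from
    both numerator and denominator.  Length 20.
``ASA``
    Relative accessible surface area per position, scaled to [0, 1] with
    pads at 0.  Length ``2n+1``.
``AAindex``
    Per-position value of one physicochemical property scale (min-max
    scaled over the 20 residues); pads and ``'X'`` at 0.  Length ``2n+1``.
``motifs``
    One bit per motif pattern: 1 iff the window satisfies every positional
    constraint of the pattern.

The module also provides the descriptive analyses used to characterise
modified sites: per-position residue frequencies, a positive-vs-negative
compositional-bias table (two-proportion z-tests), and class-wise mean ASA
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .sequence_io import (
    ALPHABET,
    AMINO_ACIDS,
    PAD,
    UNKNOWN,
    SequenceWindow,
)

_SYMBOL_INDEX = {s: i for i, s in enumerate(ALPHABET)}
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class EncodingError(ValueError):
    pass


@dataclass
class FeatureVector:
    """An ordered real vector with named, non-overlapping blocks."""

    values: np.ndarray
    blocks: list[tuple[str, int, int]]  # (name, offset, length)

    def __post_init__(self) -> None:
        total = sum(length for _, _, length in self.blocks)
        if total != len(self.values):
            raise EncodingError("block lengths do not cover the vector")
        names = [name for name, _, _ in self.blocks]
        if len(set(names)) != len(names):
            raise EncodingError("block names must be unique")

    def block(self, name: str) -> np.ndarray:
        for bname, off, length in self.blocks:
            if bname == name:
                return self.values[off : off + length]
        raise KeyError(name)


def concat_features(*vectors: FeatureVector) -> FeatureVector:
    """Concatenate feature vectors, preserving block metadata in order."""
    values = np.concatenate([v.values for v in vectors])
    blocks: list[tuple[str, int, int]] = []
    offset = 0
    for v in vectors:
        for name, off, length in v.blocks:
            blocks.append((name, offset + off, length))
        offset += len(v.values)
    return FeatureVector(values=values, blocks=blocks)


# ---------------------------------------------------------------------------
# Positional weight matrix


@dataclass
class PositionalWeightMatrix:
    """Relative symbol frequencies per window position.

    ``values`` has shape (21, w): rows are the alphabet symbols (20 amino
    acids + pad), columns the window positions.  Columns sum to 1 when every
    window is over the 21-symbol alphabet; ``'X'`` occurrences are counted
    in no row, so a column's sum drops below 1 only if unknowns are present.
    """

    values: np.ndarray
    source_count: int

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def frequency(self, symbol: str, position: int) -> float:
        if symbol == UNKNOWN:
            return 0.0
        if symbol not in _SYMBOL_INDEX:
            raise EncodingError(f"symbol {symbol!r} not in PWM alphabet")
        return float(self.values[_SYMBOL_INDEX[symbol], position])

    def to_frame(self, n: int | None = None) -> pd.DataFrame:
        w = self.width
        n = w // 2 if n is None else n
        return pd.DataFrame(
            self.values, index=list(ALPHABET), columns=range(-n, n + 1)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, source_count: int) -> "PositionalWeightMatrix":
        return cls(values=frame.to_numpy(dtype=float), source_count=source_count)


def build_pwm(windows: Sequence[SequenceWindow]) -> PositionalWeightMatrix:
    """Build a PWM from windows (conventionally the positive class)."""
    if not windows:
        raise EncodingError("cannot build a PWM from zero windows")
    w = len(windows[0].residues)
    if any(len(win.residues) != w for win in windows):
        raise EncodingError("windows have mixed lengths")
    counts = np.zeros((len(ALPHABET), w))
    for win in windows:
        for p, sym in enumerate(win.residues):
            if sym == UNKNOWN:
                continue
            counts[_SYMBOL_INDEX[sym], p] += 1
    return PositionalWeightMatrix(
        values=counts / len(windows), source_count=len(windows)
    )


def encode_pwm(
    window: SequenceWindow, pwm: PositionalWeightMatrix
) -> FeatureVector:
    """Encode a window as its per-position symbol frequencies under ``pwm``."""
    if len(window.residues) != pwm.width:
        raise EncodingError(
            f"window width {len(window.residues)} != PWM width {pwm.width}"
        )
    values = np.array(
        [pwm.frequency(sym, p) for p, sym in enumerate(window.residues)]
    )
    return FeatureVector(values=values, blocks=[("AA_PWM", 0, len(values))])


# ---------------------------------------------------------------------------
# Simple positional / compositional encoders


def encode_aa20d(window: SequenceWindow) -> FeatureVector:
    """Flattened per-position one-hot over the 21-symbol alphabet."""
    w = len(window.residues)
    values = np.zeros(len(ALPHABET) * w)
    for p, sym in enumerate(window.residues):
        if sym == UNKNOWN:
            continue
        values[p * len(ALPHABET) + _SYMBOL_INDEX[sym]] = 1.0
    return FeatureVector(values=values, blocks=[("AA_20D", 0, len(values))])


def encode_aac(window: SequenceWindow) -> FeatureVector:
    """Amino-acid composition; pads and unknowns excluded from the count."""
    counts = np.zeros(20)
    total = 0
    for sym in window.residues:
        if sym in _AA_INDEX:
            counts[_AA_INDEX[sym]] += 1
            total += 1
    values = counts / total if total else counts
    return FeatureVector(values=values, blocks=[("AAC", 0, 20)])


def encode_asa(window: SequenceWindow) -> FeatureVector:
    """Per-position relative ASA in [0, 1]; requires an ASA track."""
    if window.asa is None:
        raise EncodingError(
            f"window from {window.source} carries no ASA values; supply an "
            "ASA file or drop the ASA feature block"
        )
    values = np.asarray(window.asa, dtype=float)
    return FeatureVector(values=values, blocks=[("ASA", 0, len(values))])


# ---------------------------------------------------------------------------
# AAindex physicochemical properties


@dataclass
class AAindexEntry:
    """One physicochemical property scale: 20 values, one per residue."""

    id: str
    description: str
    values: dict[str, float]
    has_na: bool = False

    def scaled(self) -> dict[str, float]:
        """Min-max scale the 20 values to [0, 1]."""
        vals = np.array([self.values[a] for a in AMINO_ACIDS])
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            scaled = np.zeros_like(vals)
        else:
            scaled = (vals - lo) / (hi - lo)
        return dict(zip(AMINO_ACIDS, scaled.tolist()))


# AAindex1 "I" record residue order: row 1 then row 2.
_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTWYV"


def parse_aaindex(path: str | Path) -> list[AAindexEntry]:
    """Parse an AAindex1 flat file (H/D/.../I records, '//' terminators).

    Entries containing ``NA`` values are returned with ``has_na=True`` (the
    missing residues get value 0.0) and are excluded from F-score ranking by
    default.
    """
    entries: list[AAindexEntry] = []
    acc = ""
    desc = ""
    numbers: list[float] = []
    na_seen = False
    in_index = False
    with open(path) as fh:
        for line in fh:
            tag, _, rest = line.partition(" ")
            if line.startswith("H "):
                acc = rest.strip()
                desc, numbers, na_seen, in_index = "", [], False, False
            elif line.startswith("D "):
                desc = rest.strip()
            elif line.startswith("I "):
                in_index = True
            elif line.startswith("//"):
                if acc:
                    if len(numbers) != 20:
                        raise EncodingError(
                            f"AAindex entry {acc}: expected 20 values, "
                            f"got {len(numbers)}"
                        )
                    order = _AAINDEX_ROW1 + _AAINDEX_ROW2
                    entries.append(
                        AAindexEntry(
                            id=acc,
                            description=desc,
                            values=dict(zip(order, numbers)),
                            has_na=na_seen,
                        )
                    )
                acc, in_index = "", False
            elif in_index:
                for tok in line.split():
                    if tok.upper() == "NA":
                        numbers.append(0.0)
                        na_seen = True
                    else:
                        numbers.append(float(tok))
    if acc:
        raise EncodingError(f"AAindex entry {acc}: truncated record (no '//')")
    return entries


def encode_physicochemical(
    window: SequenceWindow, entry: AAindexEntry
) -> FeatureVector:
    """Encode a window under one property scale (min-max scaled values)."""
    scaled = entry.scaled()
    values = np.array(
        [scaled.get(sym, 0.0) for sym in window.residues]
    )
    return FeatureVector(
        values=values, blocks=[(f"AAindex:{entry.id}", 0, len(values))]
    )


# ---------------------------------------------------------------------------
# Motif patterns


@dataclass(frozen=True)
class MotifPattern:
    """A named conjunction of (relative position, allowed residues) constraints."""

    name: str
    constraints: frozenset[tuple[int, frozenset[str]]]

    def __post_init__(self) -> None:
        for pos, residues in self.constraints:
            if pos == 0 and residues != frozenset("C"):
                raise EncodingError(
                    f"motif {self.name!r}: a position-0 constraint must be C"
                )

    def matches(self, window: SequenceWindow) -> bool:
        for pos, residues in self.constraints:
            if window.residue_at(pos) not in residues:
                return False
        return True


def parse_motif_patterns(path: str | Path) -> list[MotifPattern]:
    """Read a motif-pattern file: ``name<TAB>pos:residues[,pos:residues...]``.

    An empty constraint field means the pattern matches every window.
    """
    patterns = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, _, spec = line.partition("\t")
            constraints = set()
            if spec.strip():
                for part in spec.split(","):
                    pos_s, _, res = part.partition(":")
                    constraints.add((int(pos_s), frozenset(res.strip())))
            patterns.append(
                MotifPattern(name=name, constraints=frozenset(constraints))
            )
    return patterns


def encode_motifs(
    window: SequenceWindow, patterns: Sequence[MotifPattern]
) -> FeatureVector:
    """Binary vector, one bit per pattern: 1 iff all constraints hold."""
    values = np.array(
        [1.0 if p.matches(window) else 0.0 for p in patterns]
    )
    return FeatureVector(values=values, blocks=[("motifs", 0, len(values))])


# ---------------------------------------------------------------------------
# sklearn-style vectorizer


class WindowVectorizer(BaseEstimator, TransformerMixin):
    """Transform sequence windows into stacked feature-block matrices.

    Parameters
    ----------
    features : tuple of str
        Ordered block names drawn from ``{"AA_20D", "AA_PWM", "AAC", "ASA",
        "motifs"}`` plus ``"AAindex:<accession>"``.  Default is the
        PWM + composition combination, the best-performing hybrid for this
        task.
    aaindex : mapping accession -> AAindexEntry, optional
    motif_patterns : sequence of MotifPattern, optional

    The PWM block is fitted on the positive windows of ``fit(X, y)`` (all
    windows when ``y`` is None).  All other blocks are stateless.
    """

    def __init__(
        self,
        features: tuple[str, ...] = ("AA_PWM", "AAC"),
        aaindex: Mapping[str, AAindexEntry] | None = None,
        motif_patterns: Sequence[MotifPattern] | None = None,
    ) -> None:
        self.features = features
        self.aaindex = aaindex
        self.motif_patterns = motif_patterns

    def fit(self, X: Sequence[SequenceWindow], y=None) -> "WindowVectorizer":
        if "AA_PWM" in self.features:
            if y is not None:
                y = np.asarray(y)
                pos = [w for w, label in zip(X, y) if label == 1]
            else:
                pos = list(X)
            if not pos:
                raise EncodingError("no positive windows to fit the PWM on")
            self.pwm_ = build_pwm(pos)
        else:
            self.pwm_ = None
        self.n_features_in_ = 1
        return self

    def _encode_one(self, window: SequenceWindow) -> FeatureVector:
        parts = []
        for name in self.features:
            if name == "AA_20D":
                parts.append(encode_aa20d(window))
            elif name == "AA_PWM":
                parts.append(encode_pwm(window, self.pwm_))
            elif name == "AAC":
                parts.append(encode_aac(window))
            elif name == "ASA":
                parts.append(encode_asa(window))
            elif name == "motifs":
                if not self.motif_patterns:
                    raise EncodingError("motif block requested but no patterns given")
                parts.append(encode_motifs(window, self.motif_patterns))
            elif name.startswith("AAindex:"):
                acc = name.split(":", 1)[1]
                if not self.aaindex or acc not in self.aaindex:
                    raise EncodingError(f"unknown AAindex accession {acc!r}")
                parts.append(encode_physicochemical(window, self.aaindex[acc]))
            else:
                raise EncodingError(f"unknown feature block {name!r}")
        return concat_features(*parts)

    def transform(self, X: Sequence[SequenceWindow]) -> np.ndarray:
        first = self._encode_one(X[0]) if len(X) else None
        if first is None:
            return np.zeros((0, 0))
        out = np.empty((len(X), len(first.values)))
        out[0] = first.values
        for i, w in enumerate(X[1:], 1):
            out[i] = self._encode_one(w).values
        return out


# ---------------------------------------------------------------------------
# Descriptive analyses


def position_frequencies(
    windows: Sequence[SequenceWindow],
) -> pd.DataFrame:
    """Per-position residue frequency table (rows = 21 symbols, columns =
    signed positions), the numeric content of a sequence-logo plot."""
    pwm = build_pwm(windows)
    return pwm.to_frame()


def composition_bias(
    positives: Sequence[SequenceWindow],
    negatives: Sequence[SequenceWindow],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Positionwise residue enrichment of positives versus negatives.

    For every flanking position (the center cysteine is skipped) and every
    standard residue, a two-proportion z-test compares the residue's
    frequency between the classes.  Rows with ``p < alpha`` are flagged
    ``enriched`` (more frequent in positives) or ``depleted``.
    """
    if not positives or not negatives:
        raise EncodingError("both classes must be non-empty")
    n = positives[0].n
    rows = []
    npos, nneg = len(positives), len(negatives)
    for offset in range(-n, n + 1):
        if offset == 0:
            continue
        for aa in AMINO_ACIDS:
            cpos = sum(w.residue_at(offset) == aa for w in positives)
            cneg = sum(w.residue_at(offset) == aa for w in negatives)
            fpos, fneg = cpos / npos, cneg / nneg
            pooled = (cpos + cneg) / (npos + nneg)
            denom = pooled * (1 - pooled) * (1 / npos + 1 / nneg)
            if denom == 0:
                p_value = 1.0
            else:
                z = (fpos - fneg) / np.sqrt(denom)
                p_value = 2 * stats.norm.sf(abs(z))
            flag = ""
            if p_value < alpha:
                flag = "enriched" if fpos > fneg else "depleted"
            rows.append(
                {
                    "position": offset,
                    "residue": aa,
                    "freq_positive": fpos,
                    "freq_negative": fneg,
                    "p_value": p_value,
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows)


def asa_profile(
    positives: Sequence[SequenceWindow],
    negatives: Sequence[SequenceWindow],
) -> pd.DataFrame:
    """Mean per-position relative ASA for each class (fractions in [0, 1]).

    Only windows carrying an ASA track contribute; pad positions contribute
    their stored 0 values, mirroring how the encoder sees them.
    """
    def class_mean(windows: Sequence[SequenceWindow]) -> np.ndarray:
        tracks = [np.asarray(w.asa) for w in windows if w.asa is not None]
        if not tracks:
            raise EncodingError("no windows with ASA values")
        return np.mean(tracks, axis=0)

    mpos = class_mean(positives)
    mneg = class_mean(negatives)
    n = len(mpos) // 2
    return pd.DataFrame(
        {
            "position": list(range(-n, n + 1)),
            "mean_asa_positive": mpos,
            "mean_asa_negative": mneg,
        }
    )
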