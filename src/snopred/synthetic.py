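"""Synthetic site datasets with planted positional motif structure.

Real S-nitrosoproteome corpora cannot be bundled, so the generator emits
datasets with the statistical structure the method exploits: proteins with
cysteines, positive sites whose flanks carry planted (position,
residue-group) preferences at a configurable penetrance — optionally
co-occurring with a partner position so that chi-square position dependence
exists — and background negatives at the reference class ratio.  Outputs
use the exact on-disk formats the I/O layer consumes (FASTA, site TSV, ASA
TSV) plus a ground-truth manifest for assertions.

Defaults mirror the reference corpus scale: 384 proteins, 586 positive
sites, a 2728/586 negative:positive ratio, and 21-mer windows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .mdd import AAGroupScheme
from .sequence_io import (
    AMINO_ACIDS,
    ProteinRecord,
    SiteAnnotation,
    SiteDataset,
    build_dataset,
    write_annotations,
    write_asa,
    write_fasta,
)

# Approximate SwissProt residue composition (percent), used as background.
SWISSPROT_COMPOSITION = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "V": 6.87, "W": 1.08, "Y": 2.92,
}


@dataclass(frozen=True)
class PlantedRule:
    """A (position, residue group) preference planted into positive flanks.

    With probability ``penetrance`` a positive site receives a residue from
    ``group`` at signed offset ``position``; if ``partner`` is given, the
    partner (position, group) is set in the same draw, creating the
    between-position dependence MDD is designed to detect.
    """

    position: int
    group: str
    penetrance: float = 1.0
    partner: tuple[int, str] | None = None

    def __post_init__(self) -> None:
        if self.position == 0:
            raise ValueError("rules cannot target the center cysteine")
        if not 0.0 < self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in (0, 1]")
        if self.partner is not None and self.partner[0] == 0:
            raise ValueError("partner cannot target the center cysteine")


@dataclass
class ASAModel:
    """Gaussian per-position ASA means (percent) for each class.

    Positives get elevated upstream exposure; the center cysteine is the
    least exposed position in both classes.
    """

    background_mean: float = 30.0
    background_sd: float = 15.0
    positive_upstream_mean: float = 45.0
    center_mean: float = 10.0


@dataclass
class SyntheticSpec:
    """Full description of one synthetic dataset."""

    n_proteins: int = 384
    n_positives: int = 586
    negative_ratio: float = 2728 / 586
    length_range: tuple[int, int] = (100, 400)
    n: int = 10
    rules: tuple[PlantedRule, ...] = ()
    #: When True, each positive site draws exactly one rule (uniformly) and
    #: applies it with that rule's penetrance — a mixture of distinct motif
    #: subpopulations.  When False, every rule fires independently.
    exclusive_rules: bool = False
    background: dict[str, float] = field(
        default_factory=lambda: dict(SWISSPROT_COMPOSITION)
    )
    asa_model: ASAModel | None = field(default_factory=ASAModel)
    seed: int = 0

    def __post_init__(self) -> None:
        positions = [r.position for r in self.rules]
        if len(positions) != len(set(positions)):
            raise ValueError("planted rules conflict at a shared position")
        if self.length_range[0] < 2 * self.n + 1:
            raise ValueError("proteins must be long enough for one window")


def _background_sampler(
    spec: SyntheticSpec, rng: np.random.Generator
):
    # Cysteines are placed only deliberately, so the background excludes C.
    letters = [a for a in AMINO_ACIDS if a != "C"]
    weights = np.array([spec.background[a] for a in letters], dtype=float)
    weights /= weights.sum()

    def sample(k: int) -> list[str]:
        return list(rng.choice(letters, size=k, p=weights))

    return sample


def generate(
    spec: SyntheticSpec,
) -> tuple[SiteDataset, dict]:
    """Generate a dataset and its ground-truth manifest.

    The manifest records, per positive site, which planted rules fired; the
    recovered penetrance of each rule matches the requested one up to
    binomial noise.  Same spec (including seed) -> identical output.
    """
    rng = np.random.default_rng(spec.seed)
    sample_bg = _background_sampler(spec, rng)
    scheme = AAGroupScheme.default()
    # planted residues never include C so cysteine placement stays deliberate
    group_members = {
        name: sorted(members - {"C"}) for name, members in scheme.groups
    }
    for rule in spec.rules:
        if rule.group not in group_members:
            raise ValueError(f"unknown residue group {rule.group!r}")
        if rule.partner and rule.partner[1] not in group_members:
            raise ValueError(f"unknown residue group {rule.partner[1]!r}")

    # distribute positives across proteins as evenly as possible
    base, extra = divmod(spec.n_positives, spec.n_proteins)
    pos_per_protein = [
        base + (1 if i < extra else 0) for i in range(spec.n_proteins)
    ]
    n_negatives = int(round(spec.negative_ratio * spec.n_positives))
    base_n, extra_n = divmod(n_negatives, spec.n_proteins)
    neg_per_protein = [
        base_n + (1 if i < extra_n else 0) for i in range(spec.n_proteins)
    ]

    proteins: list[ProteinRecord] = []
    annotations: list[SiteAnnotation] = []
    manifest_sites = []
    n = spec.n
    for i in range(spec.n_proteins):
        pid = f"SYN{i + 1:04d}"
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = sample_bg(length)
        # Sites are spaced more than n residues apart so a planted flank
        # residue can never collide with a neighbouring site's cysteine;
        # positives additionally keep a full flank inside the chain so every
        # rule target is in bounds.
        min_gap = n + 1
        taken: list[int] = []

        def place(count: int, lo: int, hi: int) -> list[int]:
            placed = []
            for cand in rng.permutation(np.arange(lo, hi + 1)):
                if len(placed) == count:
                    break
                pos = int(cand)
                if all(abs(pos - t) >= min_gap for t in taken):
                    placed.append(pos)
                    taken.append(pos)
            return placed

        pos_sites = sorted(place(pos_per_protein[i], n + 1, length - n))
        neg_sites = place(neg_per_protein[i], 1, length)
        # relax the spacing for any negatives that could not be placed
        shortfall = neg_per_protein[i] - len(neg_sites)
        if shortfall > 0:
            for cand in rng.permutation(np.arange(1, length + 1)):
                if shortfall == 0:
                    break
                pos = int(cand)
                if pos not in taken:
                    neg_sites.append(pos)
                    taken.append(pos)
                    shortfall -= 1
        neg_sites = sorted(neg_sites)
        for pos in pos_sites + neg_sites:
            seq[pos - 1] = "C"
        for pos in pos_sites:
            fired = []
            if spec.exclusive_rules and spec.rules:
                active = [spec.rules[int(rng.integers(len(spec.rules)))]]
            else:
                active = list(spec.rules)
            for rule in active:
                if rng.random() >= rule.penetrance:
                    continue
                targets = [(rule.position, rule.group)]
                if rule.partner:
                    targets.append(rule.partner)
                ok = True
                for offset, group in targets:
                    idx = pos - 1 + offset
                    if not 0 <= idx < length or seq[idx] == "C":
                        ok = False
                if not ok:
                    continue
                for offset, group in targets:
                    members = group_members[group]
                    seq[pos - 1 + offset] = members[
                        int(rng.integers(len(members)))
                    ]
                fired.append(f"{rule.position}:{rule.group}")
            manifest_sites.append(
                {"protein_id": pid, "position": pos, "rules": fired}
            )
        proteins.append(ProteinRecord(id=pid, sequence="".join(seq)))
        for pos in pos_sites:
            annotations.append(SiteAnnotation(pid, pos))

    if spec.asa_model is not None:
        _attach_asa(spec, proteins, annotations, rng)

    dataset = build_dataset(proteins, annotations, n=spec.n)
    manifest = {
        "seed": spec.seed,
        "n": spec.n,
        "n_proteins": spec.n_proteins,
        "n_positives": len(dataset.positives),
        "n_negatives": len(dataset.negatives),
        "rules": [
            {
                "position": r.position,
                "group": r.group,
                "penetrance": r.penetrance,
                "partner": list(r.partner) if r.partner else None,
            }
            for r in spec.rules
        ],
        "sites": manifest_sites,
    }
    return dataset, manifest


def _attach_asa(
    spec: SyntheticSpec,
    proteins: Sequence[ProteinRecord],
    annotations: Sequence[SiteAnnotation],
    rng: np.random.Generator,
) -> None:
    """Draw per-residue ASA percentages with class/position structure."""
    model = spec.asa_model
    assert model is not None
    pos_sites = {(a.protein_id, a.position) for a in annotations}
    n = spec.n
    for prot in proteins:
        means = np.full(len(prot.sequence), model.background_mean)
        for idx, residue in enumerate(prot.sequence):
            if residue == "C":
                means[idx] = model.center_mean
        for pid, pos in pos_sites:
            if pid != prot.id:
                continue
            lo = max(0, pos - 1 - n)
            hi = pos - 1 - 1  # upstream flank: offsets -n .. -2
            if hi >= lo:
                for idx in range(lo, hi + 1):
                    if prot.sequence[idx] != "C":
                        means[idx] = model.positive_upstream_mean
        asa = rng.normal(means, model.background_sd)
        prot.asa = np.clip(asa, 0.0, 100.0).round(2).tolist()
        ProteinRecord.__post_init__(prot)


def write_dataset(
    dataset: SiteDataset,
    manifest: dict,
    directory: str | Path,
) -> dict[str, Path]:
    """Write FASTA / sites TSV / ASA TSV / manifest JSON into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": directory / "proteins.fasta",
        "sites": directory / "sites.tsv",
        "asa": directory / "asa.tsv",
        "manifest": directory / "manifest.json",
    }
    write_fasta(dataset.proteins.values(), paths["fasta"])
    annos = [
        SiteAnnotation(w.source[0], w.source[1]) for w in dataset.positives
    ]
    write_annotations(annos, paths["sites"], with_label=False)
    if any(p.asa is not None for p in dataset.proteins.values()):
        write_asa(dataset.proteins.values(), paths["asa"])
    else:
        paths.pop("asa")
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
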