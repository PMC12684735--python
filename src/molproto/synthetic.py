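"""Synthetic molecule/text dataset generator with planted class structure.

Emulates the shape of the small-molecule benchmark suites this model family
is evaluated on: small heavy-atom graphs (mean size defaults to 13.3 atoms,
the average of a typical aqueous-solubility benchmark), binary or multi-way
class labels or a continuous target, and a short textual description per
molecule.

Each class plants a distinct structural motif — by default a five-membered
carbon ring for class 0 versus a five-carbon open chain for class 1 — and
the molecule is grown to its sampled size by attaching random tree
decorations (carbon with occasional N/O substitutions, single bonds only, so
every emitted SMILES is chemically valid).  The paired text names the motif
via a class template and appends random distractor tokens.  Regression
targets count planted motifs: ``y = alpha * count + Gaussian noise``.

Molecules are emitted as SMILES so the full parsing/featurisation path is
exercised exactly as it would be on real data.  Everything is a
deterministic function of the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .mol_io import MoleculeRecord, parse_smiles, tokenize_smiles

__all__ = ["SyntheticSpec", "generate_dataset", "dataset_to_rows"]

_DEFAULT_TEMPLATES = (
    "molecule containing a five membered carbon ring motif",
    "acyclic molecule built around a five carbon chain motif",
)

_DEFAULT_VOCAB = (
    "soluble", "lipophilic", "polar", "aromatic", "aliphatic", "branched",
    "substituted", "saturated", "heteroatom", "scaffold", "derivative",
    "compound", "fragment", "assay", "active", "inactive", "stable",
    "reactive", "small", "dense",
)

# ring motif (class 0) and chain motif (class 1), both 5 heavy atoms
_MOTIFS = ("ring5", "chain5")
_MOTIF_SIZE = 5


@dataclass
class SyntheticSpec:
    n_records: int = 400
    task_kind: str = "classification"
    n_classes: int = 2
    mean_size: float = 13.3        # mean heavy-atom count
    size_sd: float = 3.0
    label_noise: float = 0.0       # class-flip probability
    alpha: float = 1.0             # regression slope per motif count
    sigma: float = 0.1             # regression noise s.d.
    max_motif_count: int = 3       # regression: planted motifs 0..max
    templates: tuple[str, ...] = _DEFAULT_TEMPLATES
    vocabulary: tuple[str, ...] = _DEFAULT_VOCAB
    n_distractors: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.task_kind not in ("classification", "regression"):
            raise ValueError(f"unknown task_kind {self.task_kind!r}")
        if not (2 <= self.n_classes <= len(_MOTIFS)) and \
                self.task_kind == "classification":
            raise ValueError("classification supports 2 motif classes")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label noise must lie in [0, 0.5)")
        min_needed = _MOTIF_SIZE if self.task_kind == "classification" else \
            self.max_motif_count * _MOTIF_SIZE + 1
        if self.mean_size < min_needed:
            raise ValueError(
                f"mean size {self.mean_size} cannot accommodate the motif "
                f"(needs >= {min_needed} heavy atoms)")


def _sample_size(spec: SyntheticSpec, rng: np.random.Generator,
                 floor: int) -> int:
    size = int(np.floor(rng.normal(spec.mean_size, spec.size_sd) + 0.5))
    return max(size, floor)


def _add_atom(mol: Chem.RWMol, rng: np.random.Generator) -> None:
    """Attach one decoration atom by a single bond to a random open site."""
    # valence head-room under single bonds: C<=4, N<=3, O<=2
    limits = {"C": 4, "N": 3, "O": 2}
    open_sites = [a.GetIdx() for a in mol.GetAtoms()
                  if a.GetDegree() < limits[a.GetSymbol()]]
    anchor = int(rng.choice(open_sites))
    symbol = rng.choice(["C", "N", "O"], p=[0.8, 0.1, 0.1])
    new_idx = mol.AddAtom(Chem.Atom(symbol))
    mol.AddBond(anchor, new_idx, Chem.BondType.SINGLE)


def _build_molecule(motif: str, n_motifs: int, target_size: int,
                    rng: np.random.Generator) -> str:
    """Grow a molecule containing ``n_motifs`` copies of the motif plus
    random tree decoration, and emit its SMILES."""
    mol = Chem.RWMol()
    # seed atom so a zero-motif molecule is still non-empty
    if n_motifs == 0:
        mol.AddAtom(Chem.Atom("C"))
    for _ in range(n_motifs):
        base = mol.GetNumAtoms()
        for _ in range(_MOTIF_SIZE):
            mol.AddAtom(Chem.Atom("C"))
        for k in range(_MOTIF_SIZE - 1):
            mol.AddBond(base + k, base + k + 1, Chem.BondType.SINGLE)
        if motif == "ring5":
            mol.AddBond(base + _MOTIF_SIZE - 1, base, Chem.BondType.SINGLE)
        if base > 0:    # connect components into one molecule
            anchor = int(rng.integers(0, base))
            mol.AddBond(anchor, base, Chem.BondType.SINGLE)
    while mol.GetNumAtoms() < target_size:
        _add_atom(mol, rng)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def _make_text(template: str, count: int | None, rng: np.random.Generator,
               spec: SyntheticSpec) -> str:
    words = list(template.split())
    if count is not None:
        words = [f"count{count}"] + words
    distract = rng.choice(spec.vocabulary, size=spec.n_distractors,
                          replace=True)
    return " ".join(words + list(distract))


def generate_dataset(spec: SyntheticSpec) -> list[MoleculeRecord]:
    """Generate labelled molecule/text records per the spec.

    Classification alternates classes for an exactly balanced panel and
    flips each label independently with the configured noise rate (the
    planted motif always matches the *structural* class).  Regression plants
    0..max_motif_count ring motifs and sets
    ``y = alpha * count + N(0, sigma^2)``.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[MoleculeRecord] = []
    for i in range(spec.n_records):
        if spec.task_kind == "classification":
            cls = i % spec.n_classes
            size = _sample_size(spec, rng, _MOTIF_SIZE)
            smiles = _build_molecule(_MOTIFS[cls], 1, size, rng)
            label = cls
            if spec.label_noise > 0 and rng.random() < spec.label_noise:
                label = 1 - label
            text = _make_text(spec.templates[cls], None, rng, spec)
            labels = np.array([float(label)])
        else:
            count = int(rng.integers(0, spec.max_motif_count + 1))
            floor = max(count * _MOTIF_SIZE, 1) + 1
            size = _sample_size(spec, rng, floor)
            smiles = _build_molecule("ring5", count, size, rng)
            y = spec.alpha * count + rng.normal(0.0, spec.sigma)
            text = _make_text(f"molecule with {count} ring motifs",
                              count, rng, spec)
            labels = np.array([y])
        graph = parse_smiles(smiles)
        tokens = text.split() or tokenize_smiles(smiles)
        records.append(MoleculeRecord(
            smiles=smiles, graph=graph, tokens=tokens, labels=labels,
            label_mask=np.array([True]), task_kind=spec.task_kind))
    return records


def dataset_to_rows(records: list[MoleculeRecord]) -> list[dict]:
    """Rows ready for CSV export (smiles, text, label)."""
    return [{"smiles": r.smiles, "text": " ".join(r.tokens),
             "label": r.labels[0]} for r in records]
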