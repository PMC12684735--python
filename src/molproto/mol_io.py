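"""Molecular input handling: SMILES parsing into featurised graphs, labelled
CSV loading, and stratified train/test/validation splits.

A molecule is represented as a heavy-atom graph ``G = (V, E, X)``: atoms are
nodes carrying an element symbol, formal charge, aromaticity flag and degree;
bonds are undirected edges with a bond-order tag; ``X`` is a fixed-width raw
feature matrix (one-hot element over a 100-symbol vocabulary, one-hot degree
0-6, one-hot formal charge -2..+2, aromatic flag — the standard
MoleculeNet-style atom featurisation, 113 columns).

Atom indices are 0-based everywhere in code; error messages use 1-based
positions, which is how chemists count characters in a SMILES string.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

try:
    from rdkit import Chem
    from rdkit import RDLogger
    RDLogger.DisableLog("rdApp.*")
except ImportError as _err:  # pragma: no cover
    raise ImportError("molproto requires rdkit for SMILES handling") from _err

__all__ = [
    "AtomDescriptor", "MolecularGraph", "MoleculeRecord", "DatasetSplit",
    "DatasetSchema", "LoadReport", "SmilesParseError", "SchemaError",
    "parse_smiles", "featurize_atoms", "tokenize_smiles", "load_dataset",
    "load_sdf", "stratified_split", "ATOM_VOCAB", "NUM_ATOM_FEATURES",
]

# first 100 element symbols by atomic number; position = one-hot slot
ATOM_VOCAB: tuple[str, ...] = (
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr",
    "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd", "Pm", "Sm",
    "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu", "Hf", "Ta", "W",
    "Re", "Os", "Ir", "Pt", "Au", "Hg", "Tl", "Pb", "Bi", "Po", "At", "Rn",
    "Fr", "Ra", "Ac", "Th", "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf",
    "Es", "Fm",
)
_VOCAB_INDEX = {sym: i for i, sym in enumerate(ATOM_VOCAB)}

_DEGREE_SLOTS = 7          # degrees 0..6
_CHARGE_SLOTS = 5          # formal charges -2..+2
NUM_ATOM_FEATURES = len(ATOM_VOCAB) + _DEGREE_SLOTS + _CHARGE_SLOTS + 1

_SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|Si|Se|se|@@|%\d{2}|[BCNOSPFIbcnosp]|[=#$:/\\()+\-.]"
    r"|\d)"
)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed; carries a 1-based
    character position pointing at (or near) the offending token."""

    def __init__(self, smiles: str, position: int, reason: str):
        self.smiles = smiles
        self.position = position
        super().__init__(
            f"cannot parse SMILES {smiles!r}: {reason} (position {position})")


class SchemaError(ValueError):
    """Raised when a dataset file does not match the declared schema."""


@dataclass(frozen=True)
class AtomDescriptor:
    symbol: str
    formal_charge: int
    aromatic: bool
    degree: int


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph with a raw atom-feature matrix."""

    atoms: list[AtomDescriptor]
    bonds: list[tuple[int, int, str]]   # (i, j, order tag), i < j, undirected
    features: np.ndarray                # (n_atoms, NUM_ATOM_FEATURES)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def validate(self) -> None:
        n = self.n_atoms
        seen: set[tuple[int, int]] = set()
        for i, j, _order in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references a missing atom")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate undirected bond {key}")
            seen.add(key)
        if self.features.shape[0] != n:
            raise ValueError("feature row count does not match atom count")

    def adjacency(self) -> np.ndarray:
        adj = np.zeros((self.n_atoms, self.n_atoms))
        for i, j, _ in self.bonds:
            adj[i, j] = adj[j, i] = 1.0
        return adj

    def neighbors(self, v: int) -> list[int]:
        out = []
        for i, j, _ in self.bonds:
            if i == v:
                out.append(j)
            elif j == v:
                out.append(i)
        return sorted(out)


@dataclass
class MoleculeRecord:
    """One labelled molecule/text pair."""

    smiles: str
    graph: MolecularGraph
    tokens: list[str]
    labels: np.ndarray          # (n_tasks,) floats; class index for single-task
    label_mask: np.ndarray      # (n_tasks,) bool, False where label missing
    task_kind: str              # "classification" | "regression"

    @property
    def y(self) -> float:
        return float(self.labels[0])


@dataclass
class DatasetSplit:
    train: list[int]
    test: list[int]
    validation: list[int]
    seed: int
    ratios: tuple[float, float, float]

    def all_indices(self) -> list[int]:
        return sorted(self.train + self.test + self.validation)


@dataclass
class DatasetSchema:
    smiles_col: str = "smiles"
    label_cols: tuple[str, ...] = ("label",)
    text_col: str | None = "text"


@dataclass
class LoadReport:
    n_rows: int = 0
    n_loaded: int = 0
    dropped: int = 0
    dropped_rows: list[int] = field(default_factory=list)


def _syntax_scan(smiles: str) -> tuple[int, str] | None:
    """Cheap syntactic scan giving a 1-based error position for the common
    malformations (unbalanced branches/brackets, dangling ring closures).
    Returns None when the string looks syntactically plausible."""
    paren_stack: list[int] = []
    bracket_open: int | None = None
    ring_open: dict[str, int] = {}
    i = 0
    while i < len(smiles):
        ch = smiles[i]
        if bracket_open is not None:
            if ch == "]":
                bracket_open = None
            i += 1
            continue
        if ch == "(":
            paren_stack.append(i)
        elif ch == ")":
            if not paren_stack:
                return i + 1, "unmatched ')'"
            paren_stack.pop()
        elif ch == "[":
            bracket_open = i
        elif ch == "]":
            return i + 1, "unmatched ']'"
        elif ch.isdigit():
            ring_open.pop(ch, None) if ch in ring_open else \
                ring_open.update({ch: i})
        elif ch == "%":
            label = smiles[i + 1:i + 3]
            ring_open.pop(label, None) if label in ring_open else \
                ring_open.update({label: i})
            i += 2
        i += 1
    if bracket_open is not None:
        return bracket_open + 1, "unclosed '['"
    if paren_stack:
        return paren_stack[-1] + 1, "unclosed branch '('"
    if ring_open:
        pos = min(ring_open.values())
        return pos + 1, "unclosed ring bond"
    return None


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a featurised heavy-atom graph.

    Hydrogens stay implicit; atom order follows the order in which heavy
    atoms appear in the SMILES string, so parsing is deterministic.
    """
    if not smiles:
        raise SmilesParseError(smiles, 1, "empty string")
    issue = _syntax_scan(smiles)
    if issue is not None:
        raise SmilesParseError(smiles, issue[0], issue[1])
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise SmilesParseError(smiles, 1, "chemically invalid SMILES")

    atoms = [
        AtomDescriptor(
            symbol=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
            degree=a.GetDegree(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        i, j = (i, j) if i < j else (j, i)
        bonds.append((i, j, str(b.GetBondType()).lower()))
    bonds.sort()
    graph = MolecularGraph(atoms=atoms, bonds=bonds,
                           features=featurize_atoms(atoms))
    graph.validate()
    return graph


def featurize_atoms(atoms: list[AtomDescriptor]) -> np.ndarray:
    """One-hot element / degree / formal charge plus aromatic flag."""
    X = np.zeros((len(atoms), NUM_ATOM_FEATURES))
    for row, atom in enumerate(atoms):
        sym_idx = _VOCAB_INDEX.get(atom.symbol)
        if sym_idx is not None:
            X[row, sym_idx] = 1.0
        off = len(ATOM_VOCAB)
        X[row, off + min(atom.degree, _DEGREE_SLOTS - 1)] = 1.0
        off += _DEGREE_SLOTS
        charge = int(np.clip(atom.formal_charge, -2, 2))
        X[row, off + charge + 2] = 1.0
        off += _CHARGE_SLOTS
        X[row, off] = 1.0 if atom.aromatic else 0.0
    return X


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into chemically meaningful tokens (the fallback
    "textual description" when a dataset ships no text column)."""
    return [m.group(0) for m in _SMILES_TOKEN_RE.finditer(smiles)]


def _record_from_row(smiles: str, text: str | None, labels: np.ndarray,
                     mask: np.ndarray, task_kind: str) -> MoleculeRecord:
    graph = parse_smiles(smiles)
    tokens = text.split() if text else tokenize_smiles(smiles)
    if not tokens:
        tokens = tokenize_smiles(smiles)
    return MoleculeRecord(smiles=smiles, graph=graph, tokens=tokens,
                          labels=labels, label_mask=mask, task_kind=task_kind)


def load_dataset(path, schema: DatasetSchema | None = None,
                 task_kind: str = "classification",
                 delimiter: str = ",") -> tuple[list[MoleculeRecord], LoadReport]:
    """Load a labelled molecule table from CSV.

    Rows whose SMILES cannot be parsed are dropped and counted in the
    returned :class:`LoadReport`.  Missing labels (empty cells / NaN) are
    masked out, which is how multi-task toxicity panels encode unmeasured
    endpoints.
    """
    schema = schema or DatasetSchema()
    if task_kind not in ("classification", "regression"):
        raise ValueError(f"unknown task_kind: {task_kind!r}")
    df = pd.read_csv(path, sep=delimiter, encoding="utf-8")
    missing = [c for c in (schema.smiles_col, *schema.label_cols)
               if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    has_text = schema.text_col is not None and schema.text_col in df.columns

    records: list[MoleculeRecord] = []
    report = LoadReport(n_rows=len(df))
    for row_idx, row in df.iterrows():
        raw = row[list(schema.label_cols)].to_numpy()
        labels = pd.to_numeric(pd.Series(raw), errors="coerce").to_numpy(float)
        mask = np.isfinite(labels)
        if len(schema.label_cols) == 1 and not mask[0]:
            report.dropped += 1
            report.dropped_rows.append(int(row_idx))
            continue
        labels = np.where(mask, labels, 0.0)
        text = str(row[schema.text_col]) if has_text and \
            isinstance(row[schema.text_col], str) else None
        try:
            rec = _record_from_row(str(row[schema.smiles_col]), text,
                                   labels, mask, task_kind)
        except SmilesParseError:
            report.dropped += 1
            report.dropped_rows.append(int(row_idx))
            continue
        records.append(rec)
    report.n_loaded = len(records)
    return records, report


def load_sdf(path, label_prop: str,
             task_kind: str = "classification") -> tuple[list[MoleculeRecord], LoadReport]:
    """Load molecules with explicit bonds from an SDF file; the label is read
    from a molecule property field."""
    report = LoadReport()
    records: list[MoleculeRecord] = []
    for idx, mol in enumerate(Chem.SDMolSupplier(str(path))):
        report.n_rows += 1
        if mol is None or not mol.HasProp(label_prop):
            report.dropped += 1
            report.dropped_rows.append(idx)
            continue
        smiles = Chem.MolToSmiles(mol)
        labels = np.array([float(mol.GetProp(label_prop))])
        records.append(_record_from_row(smiles, None, labels,
                                        np.array([True]), task_kind))
    report.n_loaded = len(records)
    return records, report


def _strata_keys(records: list[MoleculeRecord], n_bins: int = 4) -> np.ndarray:
    """Stratum key per record: the class for single-task classification,
    quantile bin of y for regression, a single stratum otherwise."""
    first = records[0]
    if first.task_kind == "regression":
        y = np.array([r.y for r in records])
        edges = np.quantile(y, np.linspace(0, 1, n_bins + 1)[1:-1])
        return np.searchsorted(edges, y, side="right")
    if first.labels.shape[0] == 1:
        return np.array([int(r.labels[0]) for r in records])
    # multi-task panels have no single class; stratification degrades
    warnings.warn("multi-task labels: stratified split degrades to random")
    return np.zeros(len(records), dtype=int)


def stratified_split(records: list[MoleculeRecord],
                     ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                     seed: int = 0,
                     n_bins: int = 4) -> DatasetSplit:
    """Random stratified split into train/test/validation index lists.

    Class (or regression quantile-bin) proportions are preserved within
    rounding in every split; the result is a deterministic function of the
    records and the seed.  Small strata (fewer members than ``1/min(ratio)``)
    degrade the whole split to plain random with a warning.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records to split")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"split ratios must sum to 1, got {ratios}")
    keys = _strata_keys(records, n_bins=n_bins)
    min_ratio = min(r for r in ratios if r > 0)
    counts = np.bincount(keys)
    if counts[counts > 0].min() < 1.0 / min_ratio:
        warnings.warn("a stratum is too small for stratification; "
                      "falling back to a plain random split")
        keys = np.zeros(len(records), dtype=int)

    rng = np.random.default_rng(seed)
    buckets: tuple[list[int], list[int], list[int]] = ([], [], [])
    for stratum in np.unique(keys):
        idx = np.flatnonzero(keys == stratum)
        rng.shuffle(idx)
        n = len(idx)
        alloc = np.floor(np.array(ratios) * n).astype(int)
        remainder = n - alloc.sum()
        # largest-remainder apportionment; ties go to the earlier split
        frac = np.array(ratios) * n - alloc
        for slot in np.argsort(-frac, kind="stable")[:remainder]:
            alloc[slot] += 1
        start = 0
        for b, k in zip(buckets, alloc):
            b.extend(int(i) for i in idx[start:start + k])
            start += k
    train, test, validation = (sorted(b) for b in buckets)
    return DatasetSplit(train=train, test=test, validation=validation,
                        seed=seed, ratios=tuple(ratios))
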