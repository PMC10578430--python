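"""Reaction/condition dataset model and chemistry-level operations.

A reaction is stored as a reaction SMILES ``reactants>>products`` with
dot-separated molecules.  Atom indices are 0-based and follow SMILES
appearance order across the dot-separated molecules of each side
(reactants and products are numbered independently).  Atom maps, when
present, are written in the standard ``:n`` atom-map notation and are
represented in memory as an injective dict from reactant atom index to
product atom index.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

NULL_LABEL = "Null"
SLOTS = ("catalyst", "solvent1", "solvent2", "reagent1", "reagent2")
N_SLOTS = 5

#: specials of the condition vocabulary
PAD_TOKEN = "<pad>"
BOS_TOKEN = "<bos>"
EOS_TOKEN = "<eos>"

CSV_COLUMNS = ("id", "rxn_smiles") + SLOTS + ("temperature",)


class ReactionParseError(ValueError):
    """Raised when a reaction SMILES or one of its molecules cannot be parsed."""


class SchemaError(ValueError):
    """Raised for malformed dataset files or invalid configuration."""


@dataclass
class ReactionRecord:
    """One reaction with its five condition labels and optional temperature.

    ``conditions`` is the ordered 5-tuple (catalyst, solvent1, solvent2,
    reagent1, reagent2); absent conditions carry the sentinel ``"Null"``.
    ``atom_map`` maps reactant atom positions to product atom positions
    (0-based SMILES order); it is optional and must be injective.
    """

    rxn_smiles: str
    conditions: tuple[str, str, str, str, str]
    temperature: float | None = None
    atom_map: dict[int, int] | None = None
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.rxn_smiles.count(">>") != 1:
            raise ReactionParseError(
                f"reaction SMILES must contain exactly one '>>': {self.rxn_smiles!r}"
            )
        self.conditions = tuple(self.conditions)  # type: ignore[assignment]
        if len(self.conditions) != N_SLOTS:
            raise ValueError(f"conditions must have length {N_SLOTS}")
        if self.atom_map is not None:
            values = list(self.atom_map.values())
            if len(set(values)) != len(values):
                raise ValueError("atom_map must be injective")

    @property
    def reactants_smiles(self) -> str:
        return self.rxn_smiles.split(">>")[0]

    @property
    def products_smiles(self) -> str:
        return self.rxn_smiles.split(">>")[1]


@dataclass(frozen=True)
class ReactionCenter:
    """Changed-atom sets of a reaction, one per side (0-based indices)."""

    reactant_atoms: frozenset[int]
    product_atoms: frozenset[int]

    def as_pairs(self) -> frozenset[tuple[str, int]]:
        return frozenset(
            {("reactant", i) for i in self.reactant_atoms}
            | {("product", i) for i in self.product_atoms}
        )


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------

def _parse_side(side: str) -> list[Chem.Mol]:
    """Parse one side of a reaction SMILES into molecules, SMILES order kept."""
    mols = []
    for frag in side.split("."):
        mol = Chem.MolFromSmiles(frag)
        if mol is None:
            raise ReactionParseError(f"cannot parse molecule SMILES {frag!r}")
        mols.append(mol)
    return mols


def parse_reaction(rxn_smiles: str) -> tuple[list[Chem.Mol], list[Chem.Mol]]:
    if rxn_smiles.count(">>") != 1:
        raise ReactionParseError(
            f"reaction SMILES must contain exactly one '>>': {rxn_smiles!r}"
        )
    left, right = rxn_smiles.split(">>")
    return _parse_side(left), _parse_side(right)


def side_atoms(mols: Sequence[Chem.Mol]) -> list[Chem.Atom]:
    """Concatenated atom list of one side, indexing convention of the package."""
    atoms: list[Chem.Atom] = []
    for mol in mols:
        atoms.extend(mol.GetAtoms())
    return atoms


def strip_atom_maps(rxn_smiles: str) -> str:
    """Remove ``:n`` atom-map annotations, re-emitting each molecule's SMILES."""
    sides = []
    for mols in parse_reaction(rxn_smiles):
        out = []
        for mol in mols:
            mol = Chem.Mol(mol)
            for atom in mol.GetAtoms():
                atom.SetAtomMapNum(0)
            out.append(Chem.MolToSmiles(mol))
        sides.append(".".join(out))
    return ">>".join(sides)


def strip_atom_maps_with_order(
    rxn_smiles: str,
) -> tuple[str, dict[int, int], dict[int, int]]:
    """Strip ``:n`` annotations, returning old→new atom index translations.

    Molecule order is preserved; each molecule is re-emitted in canonical
    atom order.  The two dicts translate concatenated atom indices of the
    input string to indices in the returned string, one per side.
    """
    import ast

    sides_smiles: list[str] = []
    translations: list[dict[int, int]] = []
    for mols in parse_reaction(rxn_smiles):
        out: list[str] = []
        old2new: dict[int, int] = {}
        offset = 0
        for mol in mols:
            mol = Chem.Mol(mol)
            for atom in mol.GetAtoms():
                atom.SetAtomMapNum(0)
            smi = Chem.MolToSmiles(mol)
            order = ast.literal_eval(mol.GetProp("_smilesAtomOutputOrder"))
            for new_idx, old_idx in enumerate(order):
                old2new[old_idx + offset] = new_idx + offset
            out.append(smi)
            offset += mol.GetNumAtoms()
        sides_smiles.append(".".join(out))
        translations.append(old2new)
    return ">>".join(sides_smiles), translations[0], translations[1]


def strip_atom_maps_keep_center(
    rxn_smiles: str, center: "ReactionCenter"
) -> tuple[str, "ReactionCenter"]:
    """Strip ``:n`` annotations, renumbering a center to the new atom order."""
    stripped, r_map, p_map = strip_atom_maps_with_order(rxn_smiles)
    return stripped, ReactionCenter(
        frozenset(r_map[i] for i in center.reactant_atoms),
        frozenset(p_map[i] for i in center.product_atoms),
    )


def atom_map_from_smiles(rxn_smiles: str) -> dict[int, int]:
    """Derive the reactant→product atom index map from ``:n`` annotations."""
    reactants, products = parse_reaction(rxn_smiles)
    r_by_num: dict[int, int] = {}
    for idx, atom in enumerate(side_atoms(reactants)):
        num = atom.GetAtomMapNum()
        if num > 0:
            if num in r_by_num:
                raise ReactionParseError(f"duplicate atom map number {num} in reactants")
            r_by_num[num] = idx
    mapping: dict[int, int] = {}
    for idx, atom in enumerate(side_atoms(products)):
        num = atom.GetAtomMapNum()
        if num > 0 and num in r_by_num:
            mapping[r_by_num[num]] = idx
    return mapping


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def canonicalize_reaction(rxn_smiles: str) -> str:
    """Canonical form: each molecule canonicalized (atom maps dropped),
    molecules within each side sorted lexicographically.  Idempotent."""
    sides = []
    for mols in parse_reaction(rxn_smiles):
        canon = []
        for mol in mols:
            mol = Chem.Mol(mol)
            for atom in mol.GetAtoms():
                atom.SetAtomMapNum(0)
            canon.append(Chem.MolToSmiles(mol))
        sides.append(".".join(sorted(canon)))
    return ">>".join(sides)


def read_dataset(path) -> list[ReactionRecord]:
    """Read a reaction-condition CSV (schema: id, rxn_smiles, the five slots,
    optional temperature).  Empty condition cells become ``"Null"``."""
    records: list[ReactionRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file")
        missing = [c for c in CSV_COLUMNS[:-1] if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing mandatory columns {missing}")
        has_temp = "temperature" in reader.fieldnames
        for lineno, row in enumerate(reader, start=2):
            try:
                conditions = tuple(
                    (row[slot] or "").strip() or NULL_LABEL for slot in SLOTS
                )
                temp_cell = (row.get("temperature") or "").strip() if has_temp else ""
                temperature = float(temp_cell) if temp_cell else None
                records.append(
                    ReactionRecord(
                        rxn_smiles=row["rxn_smiles"].strip(),
                        conditions=conditions,  # type: ignore[arg-type]
                        temperature=temperature,
                        record_id=(row["id"] or "").strip(),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise SchemaError(f"{path}: malformed row at line {lineno}: {exc}") from exc
    return records


def write_dataset(records: Iterable[ReactionRecord], path, null_as_empty: bool = False) -> None:
    """Write records in the package CSV schema (UTF-8, header row)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            conds = [
                "" if (null_as_empty and c == NULL_LABEL) else c for c in rec.conditions
            ]
            temp = "" if rec.temperature is None else repr(float(rec.temperature))
            writer.writerow([rec.record_id, rec.rxn_smiles, *conds, temp])


def split_dataset(
    records: Sequence[ReactionRecord],
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[list[ReactionRecord], list[ReactionRecord], list[ReactionRecord]]:
    """Uniform random train/validation/test partition.

    Validation and test sizes are floor-allocated; the remainder goes to
    train.  Deterministic given ``seed``.
    """
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise SchemaError(f"split ratios must be positive and sum to 1, got {ratios}")
    n = len(records)
    n_val = int(n * ratios[1])
    n_test = int(n * ratios[2])
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    val_idx = set(order[:n_val].tolist())
    test_idx = set(order[n_val : n_val + n_test].tolist())
    train, val, test = [], [], []
    for i, rec in enumerate(records):
        (val if i in val_idx else test if i in test_idx else train).append(rec)
    return train, val, test


def _side_bonds(mols: list[Chem.Mol]) -> dict[int, set[tuple[int, float]]]:
    """Per-atom set of (neighbor index, bond order) on the concatenated scale."""
    bonds: dict[int, set[tuple[int, float]]] = {}
    offset = 0
    for mol in mols:
        for i in range(mol.GetNumAtoms()):
            bonds.setdefault(i + offset, set())
        for bond in mol.GetBonds():
            a = bond.GetBeginAtomIdx() + offset
            b = bond.GetEndAtomIdx() + offset
            order = bond.GetBondTypeAsDouble()
            bonds[a].add((b, order))
            bonds[b].add((a, order))
        offset += mol.GetNumAtoms()
    return bonds


def _changed_mapped_atoms(
    reactants: list[Chem.Mol], products: list[Chem.Mol], atom_map: dict[int, int]
) -> tuple[set[int], set[int]]:
    r_atoms = side_atoms(reactants)
    p_atoms = side_atoms(products)
    r_bonds = _side_bonds(reactants)
    p_bonds = _side_bonds(products)

    def mapped_bond_set(bonds, idx, to_product):
        # partners expressed on the product index scale so sides are comparable
        return {
            (to_product[nbr], order)
            for nbr, order in bonds[idx]
            if nbr in to_product
        }

    p_identity = {i: i for i in range(len(p_atoms))}
    changed_r: set[int] = set()
    for r_idx, p_idx in atom_map.items():
        ra, pa = r_atoms[r_idx], p_atoms[p_idx]
        if (
            ra.GetSymbol() != pa.GetSymbol()
            or ra.GetFormalCharge() != pa.GetFormalCharge()
            or ra.GetTotalNumHs() != pa.GetTotalNumHs()
            or mapped_bond_set(r_bonds, r_idx, atom_map)
            != mapped_bond_set(p_bonds, p_idx, p_identity)
        ):
            changed_r.add(r_idx)
    changed_p = {atom_map[i] for i in changed_r}
    return changed_r, changed_p


def _unmapped_closure(
    mols: list[Chem.Mol], mapped: set[int], changed: set[int]
) -> set[int]:
    """Unmapped atoms connected (through unmapped atoms) to a changed atom."""
    atoms = side_atoms(mols)
    # adjacency on the concatenated scale
    adj: dict[int, set[int]] = {i: set() for i in range(len(atoms))}
    offset = 0
    for mol in mols:
        for bond in mol.GetBonds():
            a, b = bond.GetBeginAtomIdx() + offset, bond.GetEndAtomIdx() + offset
            adj[a].add(b)
            adj[b].add(a)
        offset += mol.GetNumAtoms()
    unmapped = set(range(len(atoms))) - mapped
    frontier = {
        u for u in unmapped if adj[u] & changed
    }
    out = set()
    while frontier:
        u = frontier.pop()
        out.add(u)
        frontier |= {v for v in adj[u] & unmapped if v not in out}
    return out


def extract_reaction_center(record: ReactionRecord) -> ReactionCenter:
    """Changed-atom reaction center from an atom-mapped record.

    A mapped atom belongs to the center when its element, formal charge,
    hydrogen count, or set of bonds to mapped partners differs between
    the two sides.  Unmapped atoms (leaving/incoming groups) connected to
    a changed atom are included on their own side.
    """
    atom_map = record.atom_map
    if atom_map is None and re.search(r":\d+\]", record.rxn_smiles):
        atom_map = atom_map_from_smiles(record.rxn_smiles)
    if not atom_map:
        raise ValueError(
            "record has no atom map; obtain one from an AtomMapper first"
        )
    reactants, products = parse_reaction(record.rxn_smiles)
    changed_r, changed_p = _changed_mapped_atoms(reactants, products, atom_map)
    changed_r |= _unmapped_closure(reactants, set(atom_map), changed_r)
    changed_p |= _unmapped_closure(products, set(atom_map.values()), changed_p)
    return ReactionCenter(frozenset(changed_r), frozenset(changed_p))


def augment_reaction(record: ReactionRecord, n: int, seed: int = 0) -> list[ReactionRecord]:
    """``n`` surface-form variants: random-rooted SMILES per molecule and
    shuffled molecule order per side.  Labels and temperature are copied;
    canonicalizing any variant recovers the source reaction."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    reactants, products = parse_reaction(strip_atom_maps(record.rxn_smiles))
    out = []
    for j in range(n):
        sides = []
        for mols in (reactants, products):
            variants = []
            for mol in mols:
                root = int(rng.integers(mol.GetNumAtoms()))
                variants.append(Chem.MolToSmiles(mol, canonical=False, rootedAtAtom=root))
            order = rng.permutation(len(variants))
            sides.append(".".join(variants[i] for i in order))
        out.append(
            replace(
                record,
                rxn_smiles=">>".join(sides),
                atom_map=None,
                record_id=f"{record.record_id}_aug{j}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# condition vocabulary
# ---------------------------------------------------------------------------

@dataclass
class ConditionVocabulary:
    """Per-slot label inventories plus a shared union index.

    The union index is a bijection over all labels plus the specials
    PAD (id 0), BOS, and EOS; EOS is the only admissible id at decoder
    position 6.
    """

    per_slot_labels: tuple[list[str], ...]
    union_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.per_slot_labels) != N_SLOTS:
            raise ValueError("need one label list per slot")
        for labels in self.per_slot_labels:
            if NULL_LABEL not in labels:
                raise ValueError(f"'{NULL_LABEL}' must be present in every slot")
        if not self.union_labels:
            union = [PAD_TOKEN, BOS_TOKEN, EOS_TOKEN]
            seen = set(union)
            for labels in self.per_slot_labels:
                for lab in labels:
                    if lab not in seen:
                        union.append(lab)
                        seen.add(lab)
            self.union_labels = union
        self.index = {lab: i for i, lab in enumerate(self.union_labels)}
        if len(self.index) != len(self.union_labels):
            raise ValueError("union vocabulary has duplicate labels")

    @classmethod
    def from_records(cls, records: Iterable[ReactionRecord]) -> "ConditionVocabulary":
        slots: list[set[str]] = [set() for _ in range(N_SLOTS)]
        for rec in records:
            for s, lab in zip(slots, rec.conditions):
                s.add(lab)
        return cls(tuple(sorted(s | {NULL_LABEL}) for s in slots))

    @property
    def pad_id(self) -> int:
        return self.index[PAD_TOKEN]

    @property
    def bos_id(self) -> int:
        return self.index[BOS_TOKEN]

    @property
    def eos_id(self) -> int:
        return self.index[EOS_TOKEN]

    def __len__(self) -> int:
        return len(self.union_labels)

    def slot_ids(self, slot: int) -> list[int]:
        """Admissible union ids at decoder position ``slot`` (0..5)."""
        if slot == N_SLOTS:
            return [self.eos_id]
        return [self.index[lab] for lab in self.per_slot_labels[slot]]

    def slot_mask(self, slot: int) -> np.ndarray:
        mask = np.zeros(len(self), dtype=bool)
        mask[self.slot_ids(slot)] = True
        return mask

    def encode_conditions(self, conditions: Sequence[str]) -> np.ndarray:
        """Target sequence of 6 union ids: the 5 slot labels then EOS."""
        ids = []
        for slot, lab in enumerate(conditions):
            if lab not in self.index or self.index[lab] not in set(self.slot_ids(slot)):
                raise KeyError(f"label {lab!r} not admissible in slot {SLOTS[slot]}")
            ids.append(self.index[lab])
        ids.append(self.eos_id)
        return np.asarray(ids, dtype=np.int64)

    def to_dict(self) -> dict:
        return {
            "per_slot_labels": [list(s) for s in self.per_slot_labels],
            "union_labels": list(self.union_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditionVocabulary":
        return cls(tuple(list(s) for s in d["per_slot_labels"]), list(d["union_labels"]))
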