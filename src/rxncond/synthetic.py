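"""Template-based synthetic reaction-condition datasets.

Each template builds atom-mapped reactant molecules, derives the product
by explicit bond edits, and records the changed atoms, so every record
ships with an exact ground-truth reaction center.  Condition labels are
a deterministic function of the template identity plus one substituent
feature (presence of an electron-withdrawing group toggles solvent1), so
a model must read the molecules — not just recognize the template — and
the Bayes-optimal top-1 accuracy on noise-free data is 1 by construction.
Temperatures are Gaussian per rule, truncated to [-100, 300] °C.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem

from .chem import (
    NULL_LABEL,
    ReactionCenter,
    ReactionRecord,
    atom_map_from_smiles,
    parse_reaction,
    side_atoms,
)

# condition label inventory (SMILES-style opaque strings)
PD = "[Pd]"
PT = "[Pt]"
THF = "C1CCOC1"
ETHER = "CCOCC"
DMF = "CN(C)C=O"
DCM = "ClCCl"
ETOH = "CCO"
MEOH = "CO"
ACETONE = "CC(C)=O"
WATER = "O"
K2CO3 = "O=C([O-])[O-].[K+].[K+]"
H2 = "[H][H]"
NABH4 = "[Na+].[BH4-]"
LIALH4 = "[Li+].[AlH4-]"
EDC = "CCN=C=NCC"
ET3N = "CCN(CC)CC"

EDG_SUBS = ("", "C", "CC", "OC")
EWG_SUBS = ("F", "C(F)(F)F", "C#N")
ALKYLS = ("C", "CC", "CCC", "CC(C)C")


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ConditionRule:
    """Deterministic labels for one template; EWG toggles solvent1."""

    labels: tuple[str, str, str, str, str]
    ewg_solvent1: str
    temp_mean: float
    temp_sd: float

    def conditions(self, has_ewg: bool) -> tuple[str, str, str, str, str]:
        cat, s1, s2, r1, r2 = self.labels
        if has_ewg:
            s1 = self.ewg_solvent1
        return (cat, s1, s2, r1, r2)


@dataclass
class TemplateInstance:
    """One concrete application of a reaction template."""

    reactant_mols: list[Chem.Mol]  # atoms carry map numbers 1..N
    product_mol: Chem.Mol  # surviving atoms keep their map numbers
    changed_mapnums: set[int]  # mapped atoms whose environment changes
    deleted_mapnums: set[int]  # leaving-group atoms (reactant side only)
    has_ewg: bool


@dataclass(frozen=True)
class Template:
    name: str
    build: Callable[[np.random.Generator], TemplateInstance]


# ---------------------------------------------------------------------------
# molecule editing helpers
# ---------------------------------------------------------------------------

def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GenerationError(f"template produced invalid SMILES {smiles!r}")
    return mol


def _assign_maps(mols: Sequence[Chem.Mol]) -> list[Chem.Mol]:
    out, n = [], 1
    for mol in mols:
        mol = Chem.Mol(mol)
        for atom in mol.GetAtoms():
            atom.SetAtomMapNum(n)
            n += 1
        out.append(mol)
    return out


class _ProductEditor:
    """Edit a combined copy of the reactants into the product molecule.

    Atoms are addressed by map number, which is stable across deletions.
    """

    def __init__(self, reactant_mols: Sequence[Chem.Mol]):
        combined = reactant_mols[0]
        for mol in reactant_mols[1:]:
            combined = Chem.CombineMols(combined, mol)
        self.rw = Chem.RWMol(combined)
        self.to_delete: set[int] = set()

    def _idx(self, mapnum: int) -> int:
        for atom in self.rw.GetAtoms():
            if atom.GetAtomMapNum() == mapnum:
                return atom.GetIdx()
        raise GenerationError(f"map number {mapnum} not found")

    def set_bond(self, a: int, b: int, order: Chem.BondType) -> None:
        ia, ib = self._idx(a), self._idx(b)
        bond = self.rw.GetBondBetweenAtoms(ia, ib)
        if bond is None:
            self.rw.AddBond(ia, ib, order)
        else:
            bond.SetBondType(order)

    def set_charge(self, a: int, charge: int) -> None:
        self.rw.GetAtomWithIdx(self._idx(a)).SetFormalCharge(charge)

    def delete(self, *mapnums: int) -> None:
        self.to_delete.update(mapnums)

    def finish(self) -> Chem.Mol:
        for mapnum in sorted(self.to_delete, key=self._idx, reverse=True):
            self.rw.RemoveAtom(self._idx(mapnum))
        mol = self.rw.GetMol()
        for atom in mol.GetAtoms():
            atom.SetNoImplicit(False)
            atom.SetNumExplicitHs(0)
        Chem.SanitizeMol(mol)
        return mol


def _match_maps(mol: Chem.Mol, smarts: str) -> tuple[int, ...]:
    match = mol.GetSubstructMatch(Chem.MolFromSmarts(smarts))
    if not match:
        raise GenerationError(f"pattern {smarts!r} absent from {Chem.MolToSmiles(mol)}")
    return tuple(mol.GetAtomWithIdx(i).GetAtomMapNum() for i in match)


def _aryl(core: str, sub: str) -> str:
    """Para-substituted benzene attached to ``core`` (sub may be empty)."""
    return f"{core}c1ccc({sub})cc1" if sub else f"{core}c1ccccc1"


def _pick(rng: np.random.Generator, options: Sequence[str]) -> str:
    return options[int(rng.integers(len(options)))]


def _pick_sub(rng: np.random.Generator) -> tuple[str, bool]:
    if rng.random() < 0.35:
        return _pick(rng, EWG_SUBS), True
    return _pick(rng, EDG_SUBS), False


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

def _build_suzuki(rng: np.random.Generator) -> TemplateInstance:
    sub1, ewg1 = _pick_sub(rng)
    sub2, ewg2 = _pick_sub(rng)
    mols = _assign_maps([_mol(_aryl("Br", sub1)), _mol(_aryl("OB(O)", sub2))])
    br, ipso1 = _match_maps(mols[0], "[Br][c]")
    o1, b, o2, ipso2 = _match_maps(mols[1], "[OX2H][B]([OX2H])[c]")
    ed = _ProductEditor(mols)
    ed.set_bond(ipso1, ipso2, Chem.BondType.SINGLE)
    ed.delete(br, o1, b, o2)
    return TemplateInstance(mols, ed.finish(), {ipso1, ipso2}, {br, o1, b, o2}, ewg1 or ewg2)


def _build_ketone_reduction(rng: np.random.Generator) -> TemplateInstance:
    sub, ewg = _pick_sub(rng)
    mols = _assign_maps([_mol(_aryl(f"{_pick(rng, ALKYLS)}C(=O)", sub))])
    c, o = _match_maps(mols[0], "[CX3](=[OX1])")
    ed = _ProductEditor(mols)
    ed.set_bond(c, o, Chem.BondType.SINGLE)
    return TemplateInstance(mols, ed.finish(), {c, o}, set(), ewg)


def _build_ester_reduction(rng: np.random.Generator) -> TemplateInstance:
    sub, ewg = _pick_sub(rng)
    mols = _assign_maps([_mol(_aryl("COC(=O)", sub))])
    cme, oe, c, o = _match_maps(mols[0], "[CH3][OX2][CX3]=[OX1]")
    ed = _ProductEditor(mols)
    ed.set_bond(c, o, Chem.BondType.SINGLE)
    ed.delete(oe, cme)
    return TemplateInstance(mols, ed.finish(), {c, o}, {oe, cme}, ewg)


def _build_benzyl_deprotection(rng: np.random.Generator) -> TemplateInstance:
    sub, ewg = _pick_sub(rng)
    smi = f"c1cc(OCc2ccccc2)ccc1{sub}"
    mols = _assign_maps([_mol(smi)])
    _, o, ch2, ph = _match_maps(mols[0], "[c][OX2][CH2][c]")
    # benzyl fragment = CH2 plus everything reachable without crossing O
    mol = mols[0]
    o_idx = next(a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() == o)
    start = next(a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() == ch2)
    seen, stack = {o_idx, start}, [start]
    while stack:
        for nbr in mol.GetAtomWithIdx(stack.pop()).GetNeighbors():
            if nbr.GetIdx() not in seen:
                seen.add(nbr.GetIdx())
                stack.append(nbr.GetIdx())
    benzyl = {
        mol.GetAtomWithIdx(i).GetAtomMapNum() for i in seen - {o_idx}
    }
    ed = _ProductEditor(mols)
    ed.delete(*benzyl)
    return TemplateInstance(mols, ed.finish(), {o}, benzyl, ewg)


def _build_grignard(rng: np.random.Generator) -> TemplateInstance:
    sub, ewg = _pick_sub(rng)
    alk = _pick(rng, ("C", "CC"))
    mols = _assign_maps([_mol(_aryl("O=C", sub)), _mol(f"{alk}[Mg]Br")])
    c_ald, o = _match_maps(mols[0], "[CX3H1]=[OX1]")
    c_alk, mg = _match_maps(mols[1], "[CX4][Mg]")
    (br,) = _match_maps(mols[1], "[Br]")
    ed = _ProductEditor(mols)
    ed.set_bond(c_ald, o, Chem.BondType.SINGLE)
    ed.set_bond(c_ald, c_alk, Chem.BondType.SINGLE)
    ed.delete(mg, br)
    return TemplateInstance(mols, ed.finish(), {c_ald, o, c_alk}, {mg, br}, ewg)


def _build_amide_coupling(rng: np.random.Generator) -> TemplateInstance:
    sub, ewg = _pick_sub(rng)
    amine = _pick(rng, ("NCC", "NCc1ccccc1", "NC1CCCCC1"))
    mols = _assign_maps([_mol(_aryl("OC(=O)", sub)), _mol(amine)])
    c, o_dbl, o_oh = _match_maps(mols[0], "[CX3](=[OX1])[OX2H]")
    (n,) = _match_maps(mols[1], "[NX3;H2]")
    ed = _ProductEditor(mols)
    ed.delete(o_oh)
    ed.set_bond(c, n, Chem.BondType.SINGLE)
    return TemplateInstance(mols, ed.finish(), {c, n}, {o_oh}, ewg)


def _build_williamson_ether(rng: np.random.Generator) -> TemplateInstance:
    sub, ewg = _pick_sub(rng)
    alk = _pick(rng, ("C", "CC", "CCC"))
    mols = _assign_maps([_mol(_aryl("O", sub)), _mol(f"Br{alk}")])
    o, _ = _match_maps(mols[0], "[OX2H][c]")
    br, c = _match_maps(mols[1], "[Br][CX4]")
    ed = _ProductEditor(mols)
    ed.delete(br)
    ed.set_bond(o, c, Chem.BondType.SINGLE)
    return TemplateInstance(mols, ed.finish(), {o, c}, {br}, ewg)


def _build_nitro_reduction(rng: np.random.Generator) -> TemplateInstance:
    sub = _pick(rng, ("", "C", "OC", "F", "CC"))
    ewg = sub == "F"
    mols = _assign_maps([_mol(_aryl("O=[N+]([O-])", sub))])
    n, o1, o2 = _match_maps(mols[0], "[N+](=[OX1])[O-]")
    ed = _ProductEditor(mols)
    ed.set_charge(n, 0)
    ed.delete(o1, o2)
    return TemplateInstance(mols, ed.finish(), {n}, {o1, o2}, ewg)


DEFAULT_RULES: dict[str, ConditionRule] = {
    "suzuki_coupling": ConditionRule((PD, THF, WATER, K2CO3, NULL_LABEL), DMF, 80.0, 5.0),
    "ketone_reduction": ConditionRule((NULL_LABEL, ETOH, NULL_LABEL, NABH4, NULL_LABEL), MEOH, 25.0, 3.0),
    "ester_reduction": ConditionRule((NULL_LABEL, THF, NULL_LABEL, LIALH4, NULL_LABEL), ETHER, 0.0, 2.0),
    "benzyl_deprotection": ConditionRule((PD, ETOH, NULL_LABEL, H2, NULL_LABEL), MEOH, 25.0, 3.0),
    "grignard_addition": ConditionRule((NULL_LABEL, THF, NULL_LABEL, NULL_LABEL, NULL_LABEL), ETHER, 0.0, 5.0),
    "amide_coupling": ConditionRule((NULL_LABEL, DCM, NULL_LABEL, EDC, ET3N), DMF, 25.0, 3.0),
    "williamson_ether": ConditionRule((NULL_LABEL, ACETONE, NULL_LABEL, K2CO3, NULL_LABEL), DMF, 60.0, 5.0),
    "nitro_reduction": ConditionRule((PT, ETOH, WATER, H2, NULL_LABEL), NULL_LABEL, 50.0, 5.0),
}


def default_templates() -> list[Template]:
    """Eight organic-chemistry motifs with recorded changed atoms."""
    return [
        Template("suzuki_coupling", _build_suzuki),
        Template("ketone_reduction", _build_ketone_reduction),
        Template("ester_reduction", _build_ester_reduction),
        Template("benzyl_deprotection", _build_benzyl_deprotection),
        Template("grignard_addition", _build_grignard),
        Template("amide_coupling", _build_amide_coupling),
        Template("williamson_ether", _build_williamson_ether),
        Template("nitro_reduction", _build_nitro_reduction),
    ]


@dataclass
class GeneratorConfig:
    n_records: int = 100
    label_noise: float = 0.0
    seed: int = 0
    temp_bounds: tuple[float, float] = (-100.0, 300.0)
    templates: Optional[list[Template]] = None
    rules: Optional[dict[str, ConditionRule]] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_noise <= 1.0:
            raise ValueError("label_noise must lie in [0, 1]")


def _emit_record(
    idx: int, template: Template, inst: TemplateInstance
) -> tuple[str, ReactionCenter]:
    r_smiles = ".".join(Chem.MolToSmiles(m) for m in inst.reactant_mols)
    p_smiles = Chem.MolToSmiles(inst.product_mol)
    rxn = f"{r_smiles}>>{p_smiles}"
    reactants, products = parse_reaction(rxn)
    r_mapnums = [a.GetAtomMapNum() for a in side_atoms(reactants)]
    p_mapnums = [a.GetAtomMapNum() for a in side_atoms(products)]
    truth_r = inst.changed_mapnums | inst.deleted_mapnums
    center = ReactionCenter(
        frozenset(i for i, m in enumerate(r_mapnums) if m in truth_r),
        frozenset(i for i, m in enumerate(p_mapnums) if m in inst.changed_mapnums),
    )
    return rxn, center


def generate_dataset(
    cfg: GeneratorConfig,
) -> tuple[list[ReactionRecord], dict[str, ReactionCenter]]:
    """Generate ``cfg.n_records`` reactions with ground-truth centers.

    Deterministic given ``cfg.seed``.  Labels follow the template's rule;
    with probability ``label_noise`` a label is independently resampled
    uniformly from its slot's inventory.
    """
    rng = np.random.default_rng(cfg.seed)
    templates = cfg.templates or default_templates()
    rules = cfg.rules or DEFAULT_RULES
    slot_inventories = [
        sorted({rule.conditions(e)[s] for rule in rules.values() for e in (False, True)})
        for s in range(5)
    ]
    records, centers = [], {}
    for i in range(cfg.n_records):
        template = templates[int(rng.integers(len(templates)))]
        try:
            inst = template.build(rng)
            rxn, center = _emit_record(i, template, inst)
        except GenerationError as exc:
            raise GenerationError(f"template {template.name}: {exc}") from exc
        rule = rules[template.name]
        labels = list(rule.conditions(inst.has_ewg))
        for s in range(5):
            if rng.random() < cfg.label_noise:
                labels[s] = _pick(rng, slot_inventories[s])
        lo, hi = cfg.temp_bounds
        temp = float(rng.normal(rule.temp_mean, rule.temp_sd))
        while not lo <= temp <= hi:
            temp = float(rng.normal(rule.temp_mean, rule.temp_sd))
        record_id = f"syn{i:06d}"
        records.append(
            ReactionRecord(
                rxn_smiles=rxn,
                conditions=tuple(labels),  # type: ignore[arg-type]
                temperature=temp,
                atom_map=atom_map_from_smiles(rxn),
                record_id=record_id,
            )
        )
        centers[record_id] = center
    return records, centers


def write_centers(centers: dict[str, ReactionCenter], path) -> None:
    """Sidecar JSON of ground-truth centers (record_id → atom index lists)."""
    payload = {
        rid: {
            "reactant_atoms": sorted(c.reactant_atoms),
            "product_atoms": sorted(c.product_atoms),
        }
        for rid, c in centers.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_centers(path) -> dict[str, ReactionCenter]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return {
        rid: ReactionCenter(frozenset(d["reactant_atoms"]), frozenset(d["product_atoms"]))
        for rid, d in payload.items()
    }


def default_category_map() -> dict[str, str]:
    """Substitutability categories for the synthetic condition vocabulary.

    Used by the relaxed evaluation protocol: solvent/reagent labels in the
    same category count as a match; catalysts are always strict and Null
    only matches Null.
    """
    return {
        NULL_LABEL: NULL_LABEL,
        THF: "ether",
        ETHER: "ether",
        DMF: "polar_aprotic",
        DCM: "polar_aprotic",
        ACETONE: "polar_aprotic",
        ETOH: "alcohol",
        MEOH: "alcohol",
        WATER: "water",
        K2CO3: "base",
        ET3N: "base",
        NABH4: "hydride",
        LIALH4: "hydride",
        H2: "hydrogen",
        EDC: "coupling_agent",
        PD: PD,
        PT: PT,
    }


def pretraining_corpus(records: Sequence[ReactionRecord]) -> list[str]:
    """Condition-free reaction SMILES (atom maps stripped) for pretraining."""
    from .chem import strip_atom_maps

    return [strip_atom_maps(rec.rxn_smiles) for rec in records]
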