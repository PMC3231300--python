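"""Molecular featurization for hedonic regression.

The models in this package relate odor pleasantness to a deliberately small
feature vector: the number of non-hydrogen (heavy) atoms ``N_at`` as a proxy
for molecular size, plus binary indicators for the presence of oxygen,
sulfur, chlorine, a carboxyl group and an amine group.  Features are derived
from a SMILES string when one is available (via RDKit), or from a molecular
formula alone, in which case the structural indicators (acid, amine) are
*undetermined* — represented as ``None`` — unless explicit flags are given.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger
from rdkit.Chem import Descriptors

from .errors import FormulaError, StructureError

RDLogger.DisableLog("rdApp.*")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# carboxyl: sp2 carbon bearing a double-bonded O and a hydroxyl O
_ACID_PATTERN = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")

_PT = Chem.GetPeriodicTable()


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula into per-element counts.

    Accepts element symbols with optional integer multipliers ("C7H6O",
    "H2S").  Unknown element symbols and stray characters are rejected.
    """
    if not formula or not isinstance(formula, str):
        raise FormulaError(f"empty or non-string formula: {formula!r}")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            bad = formula[pos:match.start()]
            raise FormulaError(f"unexpected token {bad!r} in formula {formula!r}")
        symbol, mult = match.groups()
        try:
            known = _PT.GetAtomicNumber(symbol) > 0
        except Exception:
            known = False
        if not known:
            raise FormulaError(f"unknown element symbol {symbol!r} in formula {formula!r}")
        n = int(mult) if mult else 1
        if n == 0:
            raise FormulaError(f"zero multiplier for {symbol!r} in formula {formula!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = match.end()
    if pos != len(formula):
        raise FormulaError(f"unexpected token {formula[pos:]!r} in formula {formula!r}")
    if not counts:
        raise FormulaError(f"no elements found in formula {formula!r}")
    return counts


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule as supplied by the user.

    At least one of ``smiles``/``formula`` must be present.  Explicit
    acid/amine flags, when given, override structure-derived detection.
    """

    id: str
    smiles: Optional[str] = None
    formula: Optional[str] = None
    explicit_flags: Optional[Mapping[str, bool]] = None

    def __post_init__(self) -> None:
        if self.smiles is None and self.formula is None:
            raise ValueError(f"molecule {self.id!r}: need smiles or formula")


@dataclass(frozen=True)
class MolecularFeatures:
    """Feature vector of one molecule.

    ``i_acid``/``i_amine`` are tri-state: 1, 0, or ``None`` when the input
    was a bare formula and the structural question cannot be answered.
    """

    id: str
    n_at: int
    i_ox: int
    i_sul: int
    i_cl: int
    i_acid: Optional[int]
    i_amine: Optional[int]
    atom_counts: Mapping[str, int] = field(default_factory=dict)
    molecular_weight: float = 0.0

    @property
    def determined(self) -> bool:
        return self.i_acid is not None and self.i_amine is not None


def _parse_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}")
    return mol


def detect_acid(smiles: str) -> bool:
    """True iff the molecule contains a carboxyl group (C(=O)OH).

    Carboxylate anions are deliberately not matched: odorants are neutral
    volatiles, so the hydroxyl hydrogen (implicit in SMILES) is required.
    """
    return _parse_smiles(smiles).HasSubstructMatch(_ACID_PATTERN)


def _is_carbonyl_carbon(atom: Chem.Atom) -> bool:
    if atom.GetAtomicNum() != 6:
        return False
    for bond in atom.GetBonds():
        other = bond.GetOtherAtom(atom)
        if bond.GetBondType() == Chem.BondType.DOUBLE and other.GetAtomicNum() in (8, 16):
            return True
    return False


def detect_amine(smiles: str) -> bool:
    """True iff the molecule contains an amine nitrogen.

    Amine here means a neutral, non-aromatic N whose heavy neighbours are
    all carbon, bonded only by single bonds (excludes nitriles, imines,
    nitro and azide groups) and with no neighbouring carbonyl/thiocarbonyl
    carbon (excludes amides).  Aniline-type aryl amines qualify; pyridine
    ring nitrogens do not.
    """
    mol = _parse_smiles(smiles)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 7 or atom.GetFormalCharge() != 0:
            continue
        if atom.GetIsAromatic():
            continue
        neighbors = atom.GetNeighbors()
        if any(nb.GetAtomicNum() not in (1, 6) for nb in neighbors):
            continue
        if any(b.GetBondType() != Chem.BondType.SINGLE for b in atom.GetBonds()):
            continue
        if any(_is_carbonyl_carbon(nb) for nb in neighbors):
            continue
        return True
    return False


def _counts_from_mol(mol: Chem.Mol) -> dict[str, int]:
    molh = Chem.AddHs(mol)
    counts: dict[str, int] = {}
    for atom in molh.GetAtoms():
        sym = atom.GetSymbol()
        counts[sym] = counts.get(sym, 0) + 1
    return counts


def _heavy_count(counts: Mapping[str, int]) -> int:
    return sum(n for el, n in counts.items() if el != "H")


def _weight(counts: Mapping[str, int]) -> float:
    return sum(_PT.GetAtomicWeight(el) * n for el, n in counts.items())


def featurize(mol: MoleculeRecord) -> MolecularFeatures:
    """Compute the feature vector of one molecule.

    When both SMILES and formula are given their heavy-atom counts must
    agree; a mismatch raises :class:`StructureError`.  Explicit acid/amine
    flags override detection; formula-only input without flags yields
    undetermined (``None``) acid/amine indicators.
    """
    rd = None
    if mol.smiles is not None:
        rd = _parse_smiles(mol.smiles)
        counts = _counts_from_mol(rd)
        if mol.formula is not None:
            f_counts = parse_formula(mol.formula)
            if _heavy_count(f_counts) != _heavy_count(counts):
                raise StructureError(
                    f"molecule {mol.id!r}: heavy-atom count from SMILES "
                    f"({_heavy_count(counts)}) disagrees with formula "
                    f"({_heavy_count(f_counts)})"
                )
    else:
        counts = parse_formula(mol.formula)  # type: ignore[arg-type]

    flags = dict(mol.explicit_flags or {})
    if "acid" in flags:
        i_acid: Optional[int] = int(bool(flags["acid"]))
    elif rd is not None:
        i_acid = int(rd.HasSubstructMatch(_ACID_PATTERN))
    else:
        i_acid = None
    if "amine" in flags:
        i_amine: Optional[int] = int(bool(flags["amine"]))
    elif rd is not None:
        i_amine = int(detect_amine(mol.smiles))  # type: ignore[arg-type]
    else:
        i_amine = None

    i_ox = int(counts.get("O", 0) >= 1)
    if i_acid == 1 and not i_ox:
        raise StructureError(f"molecule {mol.id!r}: acid flag set but no oxygen present")
    return MolecularFeatures(
        id=mol.id,
        n_at=_heavy_count(counts),
        i_ox=i_ox,
        i_sul=int(counts.get("S", 0) >= 1),
        i_cl=int(counts.get("Cl", 0) >= 1),
        i_acid=i_acid,
        i_amine=i_amine,
        atom_counts=dict(counts),
        molecular_weight=round(_weight(counts), 4),
    )


def features_frame(feats: Iterable[MolecularFeatures]) -> pd.DataFrame:
    """Tabulate features, one row per molecule, indexed by id.

    Undetermined acid/amine indicators become NaN so that downstream design
    builders can reject them explicitly.
    """
    rows = []
    for f in feats:
        rows.append(
            {
                "id": f.id,
                "n_at": f.n_at,
                "i_ox": f.i_ox,
                "i_sul": f.i_sul,
                "i_cl": f.i_cl,
                "i_acid": float("nan") if f.i_acid is None else f.i_acid,
                "i_amine": float("nan") if f.i_amine is None else f.i_amine,
                "molecular_weight": f.molecular_weight,
            }
        )
    return pd.DataFrame(rows).set_index("id")


SUMMARY_COLUMNS = [
    "n",
    "n_at_min",
    "n_at_max",
    "n_at_mean",
    "n_oxygen",
    "n_nitrogen",
    "n_sulfur",
    "n_chlorine",
    "n_acid",
    "n_amine",
]


def summarize_set(mols: list[MoleculeRecord]) -> pd.Series:
    """Summarize a chemical set: size, N_at range, element/group counts.

    Mirrors the canonical set-composition table (n; min/max/mean heavy-atom
    count; molecules containing O, N, S, Cl; acids; amines).  Undetermined
    acid/amine indicators do not contribute to the group counts.
    """
    if not mols:
        raise ValueError("empty molecule set")
    feats = [featurize(m) for m in mols]
    nats = [f.n_at for f in feats]
    return pd.Series(
        {
            "n": len(feats),
            "n_at_min": min(nats),
            "n_at_max": max(nats),
            "n_at_mean": sum(nats) / len(nats),
            "n_oxygen": sum(f.i_ox for f in feats),
            "n_nitrogen": sum(f.atom_counts.get("N", 0) >= 1 for f in feats),
            "n_sulfur": sum(f.i_sul for f in feats),
            "n_chlorine": sum(f.i_cl for f in feats),
            "n_acid": sum(f.i_acid == 1 for f in feats),
            "n_amine": sum(f.i_amine == 1 for f in feats),
        }
    )[SUMMARY_COLUMNS]
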