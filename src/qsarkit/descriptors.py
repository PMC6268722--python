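"""The 35 connection-table (2D) descriptors used by the MLR arm.

Families: simple atom/bond counts, element-distribution entropy, Burden
(BCUT) and graph-distance (GCUT) eigenvalue descriptors weighted by PEOE
partial charge / Crippen logP / molar refractivity, a carbon-restricted
valence connectivity index, mass density over an additive van der Waals
volume, topological diameter and Petitjean shape index, PEOE-charge-binned
van der Waals surface areas (VSA), Crippen-logP-binned VSA, pharmacophore-
typed VSA sums, a distance-matrix entropy and the Oprea lead-likeness flag.

Per-atom quantities come from published open schemes: Gasteiger (PEOE)
charges with attached-hydrogen charges folded onto the heavy atom, Labute's
approximate per-atom VSA, Crippen atomic logP/MR contributions, and the
Zhao–Abraham–Zissimos additive van der Waals volume.  The named commercial
descriptors these mirror use proprietary parameterizations, so values agree
in meaning and scale but not digit-for-digit; the binned-VSA families
nevertheless satisfy their defining partition identities exactly.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, Lipinski, rdMolDescriptors
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["DESCRIPTOR_NAMES", "compute_descriptors",
           "descriptor_reference_table", "Descriptor2DCalculator"]


# --------------------------------------------------------------------------
# per-atom property helpers

def _vsa_contribs(mol) -> np.ndarray:
    contribs, _h = rdMolDescriptors._CalcLabuteASAContribs(mol)
    return np.asarray(list(contribs), dtype=float)


def _peoe_charges(mol) -> np.ndarray:
    """Gasteiger charges with implicit-H charges summed onto heavy atoms."""
    m = Chem.Mol(mol)
    AllChem.ComputeGasteigerCharges(m)
    q = np.empty(m.GetNumAtoms())
    for i, atom in enumerate(m.GetAtoms()):
        qi = atom.GetDoubleProp("_GasteigerCharge")
        if atom.HasProp("_GasteigerHCharge"):
            qi += atom.GetDoubleProp("_GasteigerHCharge")
        q[i] = qi
    return np.nan_to_num(q)


def _crippen_contribs(mol) -> tuple[np.ndarray, np.ndarray]:
    contribs = Crippen._GetAtomContribs(mol)
    logp = np.array([c[0] for c in contribs])
    mr = np.array([c[1] for c in contribs])
    return logp, mr


_ZHAO_VOL = {1: 7.24, 6: 20.58, 7: 15.60, 8: 14.71, 9: 13.31, 15: 24.43,
             16: 24.43, 17: 22.45, 35: 26.52, 53: 32.52}


def _vdw_volume(mol) -> float:
    """Zhao–Abraham–Zissimos additive vdW volume (Å³), hydrogens included.

    V = Σ atom contributions − 5.92·N_bonds − 14.7·N_aromatic_rings
        − 3.8·N_aliphatic_rings, bonds counted over all atoms incl. H.
    """
    mh = Chem.AddHs(mol)
    v = sum(_ZHAO_VOL.get(a.GetAtomicNum(), 20.0) for a in mh.GetAtoms())
    nb = mh.GetNumBonds()
    ri = mol.GetRingInfo()
    n_arom = sum(1 for ring in ri.BondRings()
                 if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring))
    n_aliph = ri.NumRings() - n_arom
    return v - 5.92 * nb - 14.7 * n_arom - 3.8 * n_aliph


def _is_acceptor(atom) -> bool:
    z = atom.GetAtomicNum()
    if z == 8:
        return True
    if z == 7:
        # pyrrole-type N (aromatic N-H donating its lone pair to the ring)
        # and quaternary/positively charged N do not accept
        if atom.GetFormalCharge() > 0:
            return False
        if atom.GetIsAromatic() and atom.GetTotalNumHs() > 0:
            return False
        return True
    return False


def _is_donor(atom) -> bool:
    return atom.GetAtomicNum() in (7, 8) and atom.GetTotalNumHs() > 0


def _burden_eigenvalues(mol, diag: np.ndarray) -> np.ndarray:
    """Sorted eigenvalues of the Burden matrix with the given diagonal.

    Off-diagonal: 0.1 × bond order for bonded pairs (aromatic = 1.5),
    0.001 for non-bonded pairs — the standard Burden construction.
    """
    n = mol.GetNumAtoms()
    B = np.full((n, n), 0.001)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        B[i, j] = B[j, i] = 0.1 * bond.GetBondTypeAsDouble()
    np.fill_diagonal(B, diag)
    return np.sort(np.linalg.eigvalsh(B))


def _gcut_eigenvalues(mol, diag: np.ndarray) -> np.ndarray:
    """Eigenvalues of the graph-distance analogue: off-diag 1/d_ij²."""
    n = mol.GetNumAtoms()
    if n == 1:
        return np.asarray(diag, dtype=float)
    D = np.asarray(Chem.GetDistanceMatrix(mol), dtype=float)
    with np.errstate(divide="ignore"):
        G = 1.0 / (D * D)
    np.fill_diagonal(G, diag)
    return np.sort(np.linalg.eigvalsh(G))


def _eig_quantile(eigs: np.ndarray, k: int) -> float:
    """The k/3 quantile position of the sorted spectrum, k in 0..3."""
    idx = int(round(k / 3 * (len(eigs) - 1)))
    return float(eigs[idx])


def _opr_violations(mol) -> int:
    """Oprea lead-like rule violations.

    Criteria: MW ≤ 450, −3.5 ≤ SlogP ≤ 4.5, rings ≤ 4, rotatable bonds
    ≤ 10, H-bond donors ≤ 5, H-bond acceptors ≤ 8.
    """
    v = 0
    v += Descriptors.MolWt(mol) > 450
    logp = Crippen.MolLogP(mol)
    v += not (-3.5 <= logp <= 4.5)
    v += mol.GetRingInfo().NumRings() > 4
    v += rdMolDescriptors.CalcNumRotatableBonds(mol) > 10
    v += Lipinski.NumHDonors(mol) > 5
    v += Lipinski.NumHAcceptors(mol) > 8
    return int(v)


# --------------------------------------------------------------------------
# descriptor functions

def _a_icm(mol) -> float:
    counts: dict[int, int] = {}
    for atom in mol.GetAtoms():
        counts[atom.GetAtomicNum()] = counts.get(atom.GetAtomicNum(), 0) + 1
        nh = atom.GetTotalNumHs()
        if nh:
            counts[1] = counts.get(1, 0) + nh
    total = sum(counts.values())
    return -sum(c / total * math.log2(c / total) for c in counts.values())


def _chi1v_c(mol) -> float:
    """Order-1 valence connectivity restricted to carbon–carbon bonds."""
    pt = Chem.GetPeriodicTable()
    dv = {}
    for atom in mol.GetAtoms():
        zv = pt.GetNOuterElecs(atom.GetAtomicNum())
        dv[atom.GetIdx()] = zv - atom.GetTotalNumHs()
    s = 0.0
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() == 6 and b.GetAtomicNum() == 6:
            prod = dv[a.GetIdx()] * dv[b.GetIdx()]
            if prod > 0:
                s += 1.0 / math.sqrt(prod)
    return s


def _vdistma(mol) -> float:
    """Entropy of the normalized graph-distance distribution.

    With m = Σ_ij D_ij: VDistMa = log2 m − Σ_ij D_ij log2 D_ij / m
    (= −Σ (D_ij/m) log2 (D_ij/m) over nonzero entries).
    """
    if mol.GetNumAtoms() < 2:
        return 0.0
    D = np.asarray(Chem.GetDistanceMatrix(mol), dtype=float)
    m = D.sum()
    nz = D[D > 0]
    return float(np.log2(m) - np.sum(nz * np.log2(nz)) / m)


_PEOE_BINS = {
    "PEOE_VSA+0": (0.00, 0.05), "PEOE_VSA+1": (0.05, 0.10),
    "PEOE_VSA+2": (0.10, 0.15), "PEOE_VSA+3": (0.15, 0.20),
    "PEOE_VSA-0": (-0.05, 0.00), "PEOE_VSA-1": (-0.10, -0.05),
}
_SLOGP_BINS = {
    # (lo, hi], per the subdivided-surface-area convention
    "SlogP_VSA1": (-0.4, -0.2), "SlogP_VSA5": (0.15, 0.20),
    "SlogP_VSA9": (0.40, math.inf),
}


def _compute_one(mol) -> dict[str, float]:
    q = _peoe_charges(mol)
    v = _vsa_contribs(mol)
    logp_at, mr_at = _crippen_contribs(mol)
    vsa_total = float(v.sum())
    D: dict[str, float] = {}

    D["a_acc"] = float(sum(_is_acceptor(a) for a in mol.GetAtoms()))
    D["a_aro"] = float(sum(a.GetIsAromatic() for a in mol.GetAtoms()))
    D["a_ICM"] = _a_icm(mol)
    D["a_nN"] = float(sum(a.GetAtomicNum() == 7 for a in mol.GetAtoms()))
    D["a_nO"] = float(sum(a.GetAtomicNum() == 8 for a in mol.GetAtoms()))
    b_heavy = mol.GetNumBonds()
    D["b_1rotR"] = (rdMolDescriptors.CalcNumRotatableBonds(mol) / b_heavy
                    if b_heavy else 0.0)

    be = _burden_eigenvalues(mol, q)
    for k in (0, 1, 2):
        D[f"BCUT_PEOE_{k}"] = _eig_quantile(be, k)
    D["GCUT_PEOE_1"] = _eig_quantile(_gcut_eigenvalues(mol, q), 1)
    ge_logp = _gcut_eigenvalues(mol, logp_at)
    D["GCUT_SLOGP_0"] = _eig_quantile(ge_logp, 0)
    D["GCUT_SLOGP_1"] = _eig_quantile(ge_logp, 1)
    D["GCUT_SMR_0"] = _eig_quantile(_gcut_eigenvalues(mol, mr_at), 0)

    D["chi1v_C"] = _chi1v_c(mol)
    D["density"] = Descriptors.MolWt(mol) / _vdw_volume(mol)

    if mol.GetNumAtoms() > 1:
        dm = np.asarray(Chem.GetDistanceMatrix(mol))
        ecc = dm.max(axis=1)
        diameter, radius = float(ecc.max()), float(ecc.min())
    else:
        diameter = radius = 0.0
    D["diameter"] = diameter
    D["petitjean"] = (diameter - radius) / radius if radius else 0.0

    D["opr_leadlike"] = float(_opr_violations(mol) < 2)

    for name, (lo, hi) in _PEOE_BINS.items():
        D[name] = float(v[(q >= lo) & (q < hi)].sum())
    D["PEOE_VSA_NEG"] = float(v[q < 0].sum())
    D["PEOE_VSA_FNEG"] = D["PEOE_VSA_NEG"] / vsa_total if vsa_total else 0.0
    D["PEOE_VSA_FHYD"] = (float(v[np.abs(q) <= 0.2].sum()) / vsa_total
                          if vsa_total else 0.0)

    D["SlogP"] = Crippen.MolLogP(mol)
    for name, (lo, hi) in _SLOGP_BINS.items():
        D[name] = float(v[(logp_at > lo) & (logp_at <= hi)].sum())

    D["VDistMa"] = _vdistma(mol)

    acc = np.array([_is_acceptor(a) for a in mol.GetAtoms()])
    don = np.array([_is_donor(a) for a in mol.GetAtoms()])
    typed = np.array([a.GetAtomicNum() in (1, 6, 7, 8, 9, 17, 35, 53)
                      for a in mol.GetAtoms()])
    D["vsa_acc"] = float(v[acc & ~don].sum())
    D["vsa_pol"] = float(v[acc & don].sum())
    D["vsa_other"] = float(v[~typed].sum())
    return D


DESCRIPTOR_NAMES = (
    "a_acc", "a_aro", "a_ICM", "a_nN", "a_nO", "b_1rotR",
    "BCUT_PEOE_0", "BCUT_PEOE_1", "BCUT_PEOE_2", "chi1v_C", "density",
    "diameter", "GCUT_PEOE_1", "GCUT_SLOGP_0", "GCUT_SLOGP_1", "GCUT_SMR_0",
    "opr_leadlike", "PEOE_VSA_FHYD", "PEOE_VSA_FNEG", "PEOE_VSA_NEG",
    "PEOE_VSA+0", "PEOE_VSA+1", "PEOE_VSA+2", "PEOE_VSA+3",
    "PEOE_VSA-0", "PEOE_VSA-1", "petitjean", "SlogP",
    "SlogP_VSA1", "SlogP_VSA5", "SlogP_VSA9", "VDistMa",
    "vsa_acc", "vsa_other", "vsa_pol",
)


def compute_descriptors(mols, names=None, ids=None) -> pd.DataFrame:
    """Descriptor matrix: one row per molecule, one column per name.

    ``names`` defaults to the full 35-descriptor catalogue; unknown names
    raise with the valid list.  Rows are indexed by ``ids`` when given.
    """
    if names is None:
        names = DESCRIPTOR_NAMES
    unknown = [n for n in names if n not in DESCRIPTOR_NAMES]
    if unknown:
        raise ValueError(f"unknown descriptor name(s) {unknown}; valid names: "
                         f"{list(DESCRIPTOR_NAMES)}")
    rows = [_compute_one(mol) for mol in mols]
    df = pd.DataFrame(rows, index=ids)[list(names)]
    if not np.isfinite(df.to_numpy()).all():
        bad = df.columns[~np.isfinite(df.to_numpy()).all(axis=0)].tolist()
        raise ValueError(f"non-finite descriptor values in columns {bad}")
    return df


_REFERENCE = {
    "a_acc": ("Number of hydrogen bond acceptor atoms", "count"),
    "a_aro": ("Number of aromatic atoms", "count"),
    "a_ICM": ("Entropy of the element distribution including implicit "
              "hydrogens", "bits"),
    "a_nN": ("Number of nitrogen atoms: #{Zi | Zi = 7}", "count"),
    "a_nO": ("Number of oxygen atoms: #{Zi | Zi = 8}", "count"),
    "b_1rotR": ("Fraction of rotatable single bonds: rotatable bond count "
                "over heavy-atom bond count", "unitless"),
    "BCUT_PEOE_0": ("Smallest eigenvalue of the PEOE-charge-weighted Burden "
                    "matrix", "e"),
    "BCUT_PEOE_1": ("1/3-quantile eigenvalue of the PEOE-charge-weighted "
                    "Burden matrix", "e"),
    "BCUT_PEOE_2": ("2/3-quantile eigenvalue of the PEOE-charge-weighted "
                    "Burden matrix", "e"),
    "chi1v_C": ("Carbon valence connectivity index (order 1)", "unitless"),
    "density": ("Molecular mass density: Weight divided by vdw_vol",
                "amu/Å^3"),
    "diameter": ("Largest value in the graph distance matrix", "bonds"),
    "GCUT_PEOE_1": ("1/3-quantile eigenvalue of the charge-weighted inverse-"
                    "squared graph-distance matrix", "e"),
    "GCUT_SLOGP_0": ("Smallest eigenvalue, atomic-logP-weighted graph-"
                     "distance matrix", "unitless"),
    "GCUT_SLOGP_1": ("1/3-quantile eigenvalue, atomic-logP-weighted graph-"
                     "distance matrix", "unitless"),
    "GCUT_SMR_0": ("Smallest eigenvalue, atomic-molar-refractivity-weighted "
                   "graph-distance matrix", "unitless"),
    "opr_leadlike": ("One if and only if opr_violation < 2 otherwise zero",
                     "boolean"),
    "PEOE_VSA_FHYD": ("Fractional hydrophobic van der Waals surface area "
                      "(|q_i| <= 0.2)", "unitless"),
    "PEOE_VSA_FNEG": ("Fractional negative van der Waals surface area",
                      "unitless"),
    "PEOE_VSA_NEG": ("Total negative van der Waals surface area", "Å^2"),
    "PEOE_VSA+0": ("Sum of v_i where q_i is in the range [0.00, 0.05)", "Å^2"),
    "PEOE_VSA+1": ("Sum of v_i where q_i is in the range [0.05, 0.10)", "Å^2"),
    "PEOE_VSA+2": ("Sum of v_i where q_i is in the range [0.10, 0.15)", "Å^2"),
    "PEOE_VSA+3": ("Sum of v_i where q_i is in the range [0.15, 0.20)", "Å^2"),
    "PEOE_VSA-0": ("Sum of v_i where q_i is in the range [-0.05, 0.00)", "Å^2"),
    "PEOE_VSA-1": ("Sum of v_i where q_i is in the range [-0.10, -0.05)", "Å^2"),
    "petitjean": ("Petitjean shape index: (diameter - radius) / radius",
                  "unitless"),
    "SlogP": ("Log of the octanol/water partition coefficient (including "
              "implicit hydrogens)", "unitless"),
    "SlogP_VSA1": ("Sum of v_i such that L_i is in (-0.4, -0.2]", "Å^2"),
    "SlogP_VSA5": ("Sum of v_i such that L_i is in (0.15, 0.20]", "Å^2"),
    "SlogP_VSA9": ("Sum of v_i such that L_i > 0.40", "Å^2"),
    "VDistMa": ("Distance-matrix entropy: log2 m - sum of D_ij log2 D_ij / m "
                "over all i, j, with m the sum of distance-matrix entries",
                "bits"),
    "vsa_acc": ("Sum of VDW surface areas of pure hydrogen bond acceptors",
                "Å^2"),
    "vsa_other": ("Sum of VDW surface areas of atoms typed 'other'", "Å^2"),
    "vsa_pol": ("Sum of VDW surface areas of polar atoms (both donor and "
                "acceptor)", "Å^2"),
}


def descriptor_reference_table() -> dict[str, tuple[str, str]]:
    """name → (definition, units) for all 35 descriptors."""
    return dict(_REFERENCE)


class Descriptor2DCalculator(TransformerMixin, BaseEstimator):
    """Transformer turning RDKit molecules into the 2D descriptor matrix."""

    def __init__(self, names=None):
        self.names = names

    def fit(self, X, y=None):
        names = self.names if self.names is not None else DESCRIPTOR_NAMES
        unknown = [n for n in names if n not in DESCRIPTOR_NAMES]
        if unknown:
            raise ValueError(f"unknown descriptor name(s): {unknown}")
        self.names_ = tuple(names)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "names_"):
            self.fit(X)
        return compute_descriptors(X, names=self.names_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.names_, dtype=object)
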