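"""Field-based 3D QSAR: conformers, alignment, lattice fields, PLS.

Pipeline: embed and minimize each structure with MMFF94 (to an RMS-gradient
target), assign MMFF94 partial charges, rigidly superimpose every conformer
onto a template over a common-core atom mapping (closed-form Kabsch), then
probe a regular lattice (2 Å spacing, 4 Å margin) with an sp³ carbon of
van der Waals radius 1.52 Å carrying +1 e:

* ``fa`` — Lennard-Jones 6-12 steric energy (CoMFA-style), truncated ±30
  kcal/mol;
* ``fe`` — Coulomb electrostatic energy with a distance-dependent
  dielectric ε = r, truncated ±30 kcal/mol;
* ``s, e, h, d, a`` — similarity-index fields (CoMSIA-style): Gaussian-
  attenuated sums of per-atom properties (r_vdw³ for steric, partial charge
  for electrostatic, Crippen atomic logP for hydrophobic, binary donor /
  acceptor typing), attenuation α = 0.3 Å⁻².

Low-variability lattice columns are removed by a standard-deviation column
filter before PLS; the model-selection matrix scans every non-empty subset
of {s,e,h,d,a} plus the CoMFA pair over column filters 1–5 kcal/mol and
reports the best leave-one-out q² per cell.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, rdFMCS

from .descriptors import _is_acceptor, _is_donor
from .pls import PLS1Regression, loo_q2_pls

__all__ = ["Conformer", "GridSpec", "FieldBlock", "embed_and_minimize",
           "align_to_template", "common_core_map", "compute_fields",
           "column_filter", "q2_matrix", "FieldQSAR",
           "SIMILARITY_FIELDS", "COMFA_FIELDS"]

SIMILARITY_FIELDS = ("s", "e", "h", "d", "a")
COMFA_FIELDS = ("fa", "fe")

PROBE_RADIUS = 1.52      # Å, sp3 carbon
PROBE_CHARGE = 1.0       # e
PROBE_EPS = 0.107        # kcal/mol, sp3 carbon well depth
ENERGY_CUTOFF = 30.0     # kcal/mol
GRID_SPACING = 2.0       # Å
GRID_MARGIN = 4.0        # Å
ATTENUATION = 0.3        # Å^-2, similarity-field Gaussian exponent
COULOMB_K = 332.0636     # kcal·Å/(mol·e²)

# per-element vdW radius (Å) and LJ well depth (kcal/mol)
_LJ_PARAMS = {1: (1.20, 0.016), 6: (1.70, 0.107), 7: (1.55, 0.095),
              8: (1.52, 0.116), 9: (1.47, 0.080), 15: (1.80, 0.200),
              16: (1.80, 0.250), 17: (1.75, 0.240), 35: (1.85, 0.300),
              53: (1.98, 0.350)}


@dataclass
class Conformer:
    """3D coordinates and MMFF94 charges for one compound (H included)."""

    compound_id: str
    mol: Chem.Mol                 # with explicit hydrogens and a conformer
    coords: np.ndarray            # (n_atoms, 3) Å
    charges: np.ndarray           # (n_atoms,) e

    def __post_init__(self):
        if not np.isfinite(self.coords).all():
            raise ValueError(f"{self.compound_id}: non-finite coordinates")
        formal = Chem.GetFormalCharge(self.mol)
        if abs(self.charges.sum() - formal) > 0.01:
            raise ValueError(
                f"{self.compound_id}: charges sum to {self.charges.sum():.3f}"
                f" but formal charge is {formal}")

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "Conformer":
        return Conformer(self.compound_id, self.mol,
                         self.coords @ R.T + t, self.charges)


def embed_and_minimize(mol, seed: int = 0, rms_gradient: float = 1e-4,
                       max_iters: int = 5000,
                       compound_id: str | None = None) -> Conformer:
    """ETKDG embedding followed by MMFF94 minimization.

    Minimization runs until the RMS gradient target (default 1e-4
    kcal/mol/Å) or the iteration cap is reached; the result is
    deterministic for a given seed.
    """
    if mol.GetNumHeavyAtoms() > 200:
        raise ValueError("molecule too large (> 200 heavy atoms)")
    cid = compound_id or (mol.GetProp("_Name") if mol.HasProp("_Name") else "?")
    mh = Chem.AddHs(Chem.Mol(mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % 2**31
    if AllChem.EmbedMolecule(mh, params) != 0:
        raise ValueError(f"3D embedding failed for compound {cid}")
    props = AllChem.MMFFGetMoleculeProperties(mh)
    if props is None:
        raise ValueError(f"MMFF94 cannot type compound {cid}")
    ff = AllChem.MMFFGetMoleculeForceField(mh, props)
    ff.Minimize(maxIts=max_iters, forceTol=rms_gradient)
    coords = mh.GetConformer().GetPositions()
    charges = np.array([props.GetMMFFPartialCharge(i)
                        for i in range(mh.GetNumAtoms())])
    return Conformer(cid, mh, np.asarray(coords, dtype=float), charges)


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation R and translation t minimizing ||P@R.T + t − Q||."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, qc - pc @ R.T


def align_to_template(conf: Conformer, template: Conformer,
                      core_map: list[tuple[int, int]]
                      ) -> tuple[Conformer, float]:
    """Rigid superposition of ``conf`` onto ``template``.

    ``core_map`` pairs (conf_atom_idx, template_atom_idx) over the common
    core (≥ 3 pairs).  Returns the transformed conformer and the RMSD over
    the mapped atoms; internal geometry is untouched.
    """
    if len(core_map) < 3:
        raise ValueError("core map needs at least 3 atom pairs")
    ci = np.array([p[0] for p in core_map])
    ti = np.array([p[1] for p in core_map])
    P = conf.coords[ci]
    Q = template.coords[ti]
    R, t = _kabsch(P, Q)
    moved = conf.transformed(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((moved.coords[ci] - Q) ** 2, axis=1))))
    return moved, rmsd


def common_core_map(conf: Conformer, template: Conformer,
                    timeout: int = 5) -> list[tuple[int, int]]:
    """Atom pairing over the maximum common substructure with the template."""
    mcs = rdFMCS.FindMCS([conf.mol, template.mol], timeout=timeout,
                         ringMatchesRingOnly=True)
    patt = Chem.MolFromSmarts(mcs.smartsString)
    if patt is None or patt.GetNumAtoms() < 3:
        raise ValueError(f"no usable common core for {conf.compound_id}")
    m1 = conf.mol.GetSubstructMatch(patt)
    m2 = template.mol.GetSubstructMatch(patt)
    return list(zip(m1, m2))


@dataclass
class GridSpec:
    origin: np.ndarray            # (3,) Å
    shape: tuple[int, int, int]
    spacing: float = GRID_SPACING

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    @classmethod
    def from_conformers(cls, confs, spacing: float = GRID_SPACING,
                        margin: float = GRID_MARGIN) -> "GridSpec":
        allc = np.vstack([c.coords for c in confs])
        lo = allc.min(axis=0) - margin
        hi = allc.max(axis=0) + margin
        lo = np.floor(lo / spacing) * spacing
        shape = tuple(int(np.ceil((h - l) / spacing)) + 1
                      for l, h in zip(lo, hi))
        return cls(origin=lo, shape=shape, spacing=spacing)

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    def points(self) -> np.ndarray:
        ax = [self.origin[k] + self.spacing * np.arange(self.shape[k])
              for k in range(3)]
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack([a.ravel() for a in g], axis=1)


@dataclass
class FieldBlock:
    """Molecules × (lattice points × field types) matrix with column labels."""

    grid: GridSpec
    fields: tuple
    matrix: np.ndarray            # (n_mols, n_cols)
    col_fields: np.ndarray        # (n_cols,) field label per column
    col_points: np.ndarray        # (n_cols,) lattice point index per column
    ids: list = field(default_factory=list)

    def select_fields(self, subset) -> "FieldBlock":
        subset = tuple(subset)
        unknown = [f for f in subset if f not in self.fields]
        if unknown:
            raise ValueError(f"fields not computed: {unknown}")
        mask = np.isin(self.col_fields, subset)
        return FieldBlock(self.grid, subset, self.matrix[:, mask],
                          self.col_fields[mask], self.col_points[mask],
                          self.ids)


def _atom_lj(mol) -> tuple[np.ndarray, np.ndarray]:
    r = np.empty(mol.GetNumAtoms())
    e = np.empty(mol.GetNumAtoms())
    for i, a in enumerate(mol.GetAtoms()):
        r[i], e[i] = _LJ_PARAMS.get(a.GetAtomicNum(), (1.70, 0.10))
    return r, e


def compute_fields(confs: list[Conformer], grid: GridSpec | None = None,
                   fields=SIMILARITY_FIELDS + COMFA_FIELDS) -> FieldBlock:
    """Evaluate the requested fields for aligned conformers on the lattice."""
    if grid is None:
        grid = GridSpec.from_conformers(confs)
    pts = grid.points()
    n_pts = len(pts)
    blocks = {f: np.empty((len(confs), n_pts)) for f in fields}
    for m, conf in enumerate(confs):
        d2 = np.sum((pts[:, None, :] - conf.coords[None, :, :]) ** 2, axis=2)
        d2 = np.maximum(d2, 1e-12)
        d = np.sqrt(d2)
        if "fa" in fields or "fe" in fields:
            if "fa" in fields:
                r_a, eps_a = _atom_lj(conf.mol)
                r0 = PROBE_RADIUS + r_a          # Lorentz
                eps = np.sqrt(PROBE_EPS * eps_a)  # Berthelot
                frac6 = (r0[None, :] ** 2 / d2) ** 3
                lj = eps[None, :] * (frac6 ** 2 - 2.0 * frac6)
                blocks["fa"][m] = np.clip(lj.sum(axis=1),
                                          -ENERGY_CUTOFF, ENERGY_CUTOFF)
            if "fe" in fields:
                # distance-dependent dielectric eps = r  =>  E ~ q/r^2
                coul = COULOMB_K * PROBE_CHARGE * conf.charges[None, :] / d2
                blocks["fe"][m] = np.clip(coul.sum(axis=1),
                                          -ENERGY_CUTOFF, ENERGY_CUTOFF)
        if set(fields) & set(SIMILARITY_FIELDS):
            att = np.exp(-ATTENUATION * d2)
            if "s" in fields:
                r_a, _ = _atom_lj(conf.mol)
                blocks["s"][m] = -(att * (r_a ** 3)[None, :]).sum(axis=1)
            if "e" in fields:
                blocks["e"][m] = -(att * conf.charges[None, :]).sum(axis=1)
            if "h" in fields:
                logp = np.array([c[0] for c in Crippen._GetAtomContribs(conf.mol)])
                blocks["h"][m] = -(att * logp[None, :]).sum(axis=1)
            if "d" in fields or "a" in fields:
                don = np.array([_is_donor(a) for a in conf.mol.GetAtoms()],
                               dtype=float)
                acc = np.array([_is_acceptor(a) for a in conf.mol.GetAtoms()],
                               dtype=float)
                if "d" in fields:
                    blocks["d"][m] = -(att * don[None, :]).sum(axis=1)
                if "a" in fields:
                    blocks["a"][m] = -(att * acc[None, :]).sum(axis=1)
    matrix = np.hstack([blocks[f] for f in fields])
    col_fields = np.concatenate([np.full(n_pts, f, dtype=object)
                                 for f in fields])
    col_points = np.concatenate([np.arange(n_pts)] * len(fields))
    return FieldBlock(grid, tuple(fields), matrix, col_fields, col_points,
                      [c.compound_id for c in confs])


def column_filter(block: FieldBlock, sigma_threshold: float) -> FieldBlock:
    """Drop lattice columns whose SD across molecules is below threshold."""
    if sigma_threshold < 0:
        raise ValueError("threshold must be nonnegative")
    sd = block.matrix.std(axis=0, ddof=0)
    keep = sd >= sigma_threshold if sigma_threshold > 0 else np.ones_like(sd, bool)
    if not keep.any():
        raise ValueError(
            f"column filter {sigma_threshold} removed every column")
    return FieldBlock(block.grid, block.fields, block.matrix[:, keep],
                      block.col_fields[keep], block.col_points[keep],
                      block.ids)


def field_subset_labels() -> list[str]:
    """The 32 canonical row labels: all subsets of s,e,h,d,a then CoMFA."""
    labels = []
    for r in range(1, 6):
        for combo in itertools.combinations(SIMILARITY_FIELDS, r):
            labels.append(".".join(combo))
    labels.append("CoMFA")
    return labels


def q2_matrix(block_full: FieldBlock, y, filters=(1, 2, 3, 4, 5),
              max_components: int = 6) -> pd.DataFrame:
    """LOO-q² model-selection matrix: 32 field subsets × column filters.

    Each cell holds the best LOO q² over PLS component counts up to the
    cap, computed on the column-filtered submatrix of that field subset.
    A cell whose filter removes every column reports 0.0 (mean-only model).
    The chosen component count per cell is stored in
    ``result.attrs['components']``; the overall argmax in
    ``result.attrs['best']``.
    """
    missing = [f for f in SIMILARITY_FIELDS + COMFA_FIELDS
               if f not in block_full.fields]
    if missing:
        raise ValueError(f"q2 matrix needs all fields computed; missing "
                         f"{missing}")
    y = np.asarray(y, dtype=float).ravel()
    labels = field_subset_labels()
    out = pd.DataFrame(index=labels, columns=list(filters), dtype=float)
    comps = pd.DataFrame(index=labels, columns=list(filters), dtype=float)
    best = (-np.inf, None)
    for label in labels:
        subset = COMFA_FIELDS if label == "CoMFA" else tuple(label.split("."))
        sub = block_full.select_fields(subset)
        sd = sub.matrix.std(axis=0, ddof=0)
        for thr in filters:
            keep = sd >= thr
            if not keep.any():
                out.loc[label, thr] = 0.0
                comps.loc[label, thr] = 0
                continue
            k, q2, _se, _ = loo_q2_pls(sub.matrix[:, keep], y, max_components)
            out.loc[label, thr] = q2
            comps.loc[label, thr] = k
            if q2 > best[0]:
                best = (q2, (label, thr, k))
    out.attrs["components"] = comps
    out.attrs["best"] = best[1]
    return out


class FieldQSAR(PLS1Regression):
    """PLS regressor over a column-filtered field block.

    A thin estimator for one (field subset, column filter) configuration;
    :func:`q2_matrix` is the scan that picks the configuration.  Fit takes
    the *full* FieldBlock and the activity vector; prediction takes a
    FieldBlock computed on the same grid.
    """

    def __init__(self, fields=("s",), sigma_threshold: float = 1.0,
                 n_components: int = 4):
        super().__init__(n_components=n_components)
        self.fields = fields
        self.sigma_threshold = sigma_threshold

    def fit(self, X: FieldBlock, y):
        sub = X.select_fields(self.fields)
        sd = sub.matrix.std(axis=0, ddof=0)
        self.keep_ = sd >= self.sigma_threshold
        if not self.keep_.any():
            raise ValueError("column filter removed every column")
        self.grid_ = sub.grid
        super().fit(sub.matrix[:, self.keep_], y)
        y = np.asarray(y, dtype=float).ravel()
        fitted = super().predict(sub.matrix[:, self.keep_])
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r2_ = 1.0 - float(np.sum((y - fitted) ** 2)) / ss_tot
        return self

    def predict(self, X, n_components=None):
        if isinstance(X, FieldBlock):
            X = X.select_fields(self.fields).matrix[:, self.keep_]
        return super().predict(X, n_components=n_components)
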