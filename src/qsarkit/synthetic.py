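"""Synthetic congeneric compound series with a known structure–activity model.

Real benchmark sets for fused-polycyclic topoisomerase inhibitors exist only
as printed figures, so every downstream stage here is exercised on generated
series instead: a handful of shared scaffolds decorated at fixed attachment
points with substituents drawn from a small fragment alphabet, activities
produced by a known linear model over substructure counts (plus Gaussian
noise) on the negative-log scale, and per-endpoint missingness mirroring the
uneven assay coverage typical of literature-collected bioactivity data.

The ground-truth model makes the generator double as an oracle: with zero
noise a fragment-count regression must recover the planted weights exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

__all__ = [
    "ScaffoldSpec", "TrueModel", "CompoundRecord",
    "generate_library", "generate_dataset", "assign_activities",
    "inject_missingness", "write_sdf", "write_activities_csv",
    "example_scaffolds", "example_true_model", "GROUP_COUNTS_RPMI",
]

#: per-skeleton compound counts of the RPMI-like endpoint (133 compounds)
GROUP_COUNTS_RPMI = (65, 9, 13, 6, 10, 30)

#: endpoint availability fractions emulating uneven literature coverage,
#: relative to the 133-compound full set
ENDPOINT_AVAILABILITY = {
    "RPMI8402": 1.0,
    "CPT-K5": 101 / 133,
    "P388": 82 / 133,
    "CPT45": 73 / 133,
    "KB3-1": 83 / 133,
    "KBV-1": 81 / 133,
    "KBH5.0": 60 / 133,
    "TOP-I": 94 / 133,
}


@dataclass(frozen=True)
class ScaffoldSpec:
    """A scaffold with numbered attachment points and a substituent alphabet.

    ``scaffold`` is a SMILES containing dummy atoms ``[*:k]`` marking each
    attachment site; ``substituents`` are fragment SMILES each carrying a
    single unnumbered ``[*]`` (use ``[*][H]`` for hydrogen).  ``positions``
    lists the atom-map numbers of the attachment sites.
    """

    scaffold: str
    substituents: tuple[str, ...]
    name: str = "G?"
    positions: tuple[int, ...] = ()

    def __post_init__(self):
        mol = Chem.MolFromSmiles(self.scaffold)
        if mol is None:
            raise ValueError(f"unparsable scaffold SMILES: {self.scaffold!r}")
        maps = sorted(a.GetAtomMapNum() for a in mol.GetAtoms()
                      if a.GetAtomicNum() == 0)
        if not maps:
            raise ValueError(
                f"scaffold {self.scaffold!r} has no [*:k] attachment point")
        if len(set(maps)) != len(maps):
            raise ValueError("attachment-point map numbers must be distinct")
        if not self.positions:
            object.__setattr__(self, "positions", tuple(maps))
        elif tuple(sorted(self.positions)) != tuple(maps):
            raise ValueError("positions do not match scaffold map numbers")
        if not self.substituents:
            raise ValueError("substituent list must be non-empty")
        for s in self.substituents:
            if _parse_fragment(s) is None:
                raise ValueError(f"unparsable substituent SMILES: {s!r}")

    @property
    def n_combinations(self) -> int:
        return len(self.substituents) ** len(self.positions)


@dataclass(frozen=True)
class TrueModel:
    """Planted linear structure–activity model.

    activity = intercept + Σ_f weight_f · count(f) + N(0, noise_sd²),
    with counts of SMARTS substructure matches and activity already on the
    negative-log (pIC50-like) scale.
    """

    feature_weights: dict
    intercept: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not any(w != 0 for w in self.feature_weights.values()):
            raise ValueError("at least one feature weight must be nonzero")
        for patt in self.feature_weights:
            if Chem.MolFromSmarts(patt) is None:
                raise ValueError(f"unparsable SMARTS pattern: {patt!r}")


@dataclass
class CompoundRecord:
    id: str
    mol: Chem.Mol
    group: str = "unassigned"
    mol_weight: float = field(default=0.0)

    def __post_init__(self):
        if self.mol_weight == 0.0 and self.mol is not None:
            self.mol_weight = Descriptors.MolWt(self.mol)

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


def _parse_fragment(smiles: str):
    frag = Chem.MolFromSmiles(smiles, sanitize=False)
    if frag is None:
        return None
    try:
        Chem.SanitizeMol(frag)
    except Exception:
        return None
    stars = [a for a in frag.GetAtoms() if a.GetAtomicNum() == 0]
    if len(stars) != 1:
        return None
    return frag


def _attach(scaffold_mol: Chem.Mol, frags: dict[int, str]) -> Chem.Mol:
    """Zip substituent fragments onto the scaffold's numbered dummy atoms."""
    combo = Chem.RWMol(scaffold_mol)
    for map_num, frag_smiles in frags.items():
        frag = Chem.Mol(_parse_fragment(frag_smiles))
        for a in frag.GetAtoms():
            if a.GetAtomicNum() == 0:
                a.SetAtomMapNum(map_num)
        combo = Chem.RWMol(Chem.CombineMols(combo, frag))
    zipped = Chem.molzip(combo)
    zipped = Chem.RemoveHs(zipped)
    Chem.SanitizeMol(zipped)
    return zipped


def generate_library(spec: ScaffoldSpec, n: int, seed: int,
                     replace: bool = False, id_prefix: str | None = None
                     ) -> list[CompoundRecord]:
    """Draw ``n`` substituted variants of one scaffold, deterministically.

    Combinations of substituents over the attachment sites are sampled
    without replacement by default, so all structures are distinct; set
    ``replace=True`` to allow repeats when n exceeds the combination space.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    total = spec.n_combinations
    if not replace and n > total:
        raise ValueError(
            f"n={n} exceeds the {total} distinct substituent combinations "
            f"of scaffold {spec.name}; pass replace=True to sample with "
            "replacement")
    rng = np.random.default_rng(seed)
    codes = rng.choice(total, size=n, replace=replace)
    scaffold_mol = Chem.MolFromSmiles(spec.scaffold)
    n_sites = len(spec.positions)
    n_subs = len(spec.substituents)
    prefix = id_prefix if id_prefix is not None else spec.name
    records = []
    for j, code in enumerate(codes):
        digits = []
        c = int(code)
        for _ in range(n_sites):
            digits.append(c % n_subs)
            c //= n_subs
        frags = {pos: spec.substituents[d]
                 for pos, d in zip(spec.positions, digits)}
        mol = _attach(scaffold_mol, frags)
        rec = CompoundRecord(id=f"{prefix}-{j:03d}", mol=mol, group=spec.name)
        records.append(rec)
    return records


def generate_dataset(specs: list[ScaffoldSpec], counts: list[int], seed: int
                     ) -> list[CompoundRecord]:
    """A multi-scaffold library: ``counts[i]`` compounds from ``specs[i]``."""
    if len(specs) != len(counts):
        raise ValueError("specs and counts differ in length")
    ss = np.random.SeedSequence(seed).spawn(len(specs))
    records = []
    for spec, cnt, child in zip(specs, counts, ss):
        records.extend(generate_library(spec, cnt,
                                        seed=int(child.generate_state(1)[0] % 2**31)))
    return records


def assign_activities(records: list[CompoundRecord], model: TrueModel,
                      seed: int, endpoint: str = "activity") -> pd.DataFrame:
    """Activities from the planted model; one column per endpoint, id index."""
    patterns = {p: Chem.MolFromSmarts(p) for p in model.feature_weights}
    rng = np.random.default_rng(seed)
    vals = []
    for rec in records:
        a = model.intercept
        for patt, w in model.feature_weights.items():
            a += w * len(rec.mol.GetSubstructMatches(patterns[patt]))
        vals.append(a)
    vals = np.asarray(vals, dtype=float)
    if model.noise_sd > 0:
        vals = vals + rng.normal(0.0, model.noise_sd, size=len(vals))
    return pd.DataFrame({endpoint: vals}, index=[r.id for r in records])


def noiseless_activity(rec: CompoundRecord, model: TrueModel) -> float:
    """The deterministic part of the planted model for one compound."""
    a = model.intercept
    for patt, w in model.feature_weights.items():
        a += w * len(rec.mol.GetSubstructMatches(Chem.MolFromSmarts(patt)))
    return a


def inject_missingness(table: pd.DataFrame, availability: dict, seed: int
                       ) -> pd.DataFrame:
    """Blank a deterministic random subset of each endpoint column.

    ``availability`` maps endpoint name to the fraction of compounds whose
    value is retained; round(fraction·n) values survive, the rest are NaN.
    """
    out = table.copy()
    rng = np.random.default_rng(seed)
    n = len(table)
    for endpoint, frac in availability.items():
        if endpoint not in table.columns:
            raise KeyError(f"unknown endpoint: {endpoint!r}")
        if not 0 < frac <= 1:
            raise ValueError(f"availability fraction for {endpoint} must be "
                             "in (0, 1]")
        keep = int(np.rint(frac * n))
        kept = rng.choice(n, size=keep, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[kept] = False
        out.iloc[mask, out.columns.get_loc(endpoint)] = np.nan
    return out


def write_sdf(records: list[CompoundRecord], path) -> None:
    """V2000 SDF with the record id as the molecule title."""
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    for rec in records:
        mol = Chem.Mol(rec.mol)
        mol.SetProp("_Name", rec.id)
        mol.SetProp("group", rec.group)
        writer.write(mol)
    writer.close()


def write_activities_csv(table: pd.DataFrame, path) -> None:
    """Long-format CSV: compound_id, endpoint, value (missing rows omitted)."""
    long = (table.rename_axis("compound_id").reset_index()
            .melt(id_vars="compound_id", var_name="endpoint", value_name="value")
            .dropna(subset=["value"]))
    long.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Default study conditions

_SUBSTITUENTS = ("[*][H]", "[*]C", "[*]OC", "[*]O", "[*]Cl", "[*]N(C)C",
                 "[*]C#N", "[*]CCO", "[*]OCC", "[*]F", "[*]N", "[*]CN(C)C")


def example_scaffolds() -> list[ScaffoldSpec]:
    """Six fused-ring scaffold groups with two substitution sites each.

    Modest bi-/tricyclic aza-aromatics standing in for a congeneric
    polycyclic inhibitor series; all share an aromatic N like the
    phenanthridine core family they emulate.
    """
    smis = [
        ("G1", "Cc1cc2ccc3cc([*:1])c([*:2])cc3c2cn1"),
        ("G2", "c1nc2cc([*:1])c([*:2])cc2cn1"),
        ("G3", "c1cc2c(ncc([*:1])c2[*:2])cc1"),
        ("G4", "c1cc2cc3ccncc3c([*:1])c2c(c1)[*:2]"),
        ("G5", "c1cc2[nH]c3cc([*:1])c([*:2])cc3c2cc1"),
        ("G6", "c1cnc2cc3c(cc2c1)cc([*:1])c(c3)[*:2]"),
    ]
    return [ScaffoldSpec(scaffold=s, substituents=_SUBSTITUENTS, name=n)
            for n, s in smis]


def example_true_model(noise_sd: float = 0.3) -> TrueModel:
    """Planted SAR on the negative-log scale.

    Methoxy/amino substitution and overall nitrogen content raise potency,
    chlorine lowers it: an idealized cartoon of the alkoxy/amine preference
    such inhibitor series display.
    """
    return TrueModel(
        feature_weights={
            "[OX2][CH3]": 0.6,     # methoxy
            "[NX3;!$([nX3])]": 0.5,  # aliphatic amine N
            "Cl": -0.4,
            "[n]": 0.25,           # aromatic nitrogen
            "C#N": -0.2,
        },
        intercept=0.5,
        noise_sd=noise_sd,
    )
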