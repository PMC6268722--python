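"""Dataset ingestion, negative-log transform, skeleton grouping and splits.

Structures arrive as SDF (or SMILES+CSV), activities as a long CSV
(compound_id, endpoint, value).  Raw REC/IC50 concentrations are converted
to the negative-log scale (pREC/pIC50) after unit normalization to molar.
The training/external split protocol sorts compounds by molecular weight,
bins them into weight deciles and samples the training set stratified over
the bins, repeated with independent seeds — so every repeat spans the full
weight (and hence size/lipophilicity) range of the series.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .synthetic import CompoundRecord

ENDPOINTS = ("RPMI8402", "CPT-K5", "P388", "CPT45", "KB3-1", "KBV-1",
             "KBH5.0", "TOP-I")

_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9,
                  "pM": 1e-12, "ratio": 1.0}


@dataclass
class SplitPlan:
    repeat: int
    train_ids: list
    test_ids: list
    seed: int

    def __post_init__(self):
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


def read_dataset(structures_path, activities_path,
                 endpoints: tuple | None = None
                 ) -> tuple[list[CompoundRecord], pd.DataFrame]:
    """Read an SDF (or .smi) and a long activity CSV; join on compound id.

    Returns the compound records and a wide activity table (id index, one
    column per endpoint, NaN where missing).  CSV rows whose id matches no
    structure are dropped with a warning count attached to the table
    (``table.attrs['n_unmatched']``).
    """
    structures_path = Path(structures_path)
    records = []
    seen = set()
    if structures_path.suffix.lower() in {".smi", ".smiles"}:
        for i, line in enumerate(structures_path.read_text().splitlines()):
            if not line.strip():
                continue
            parts = line.split()
            mol = Chem.MolFromSmiles(parts[0])
            if mol is None:
                raise ValueError(f"unparsable SMILES at line {i + 1}")
            cid = parts[1] if len(parts) > 1 else f"cmpd-{i}"
            records.append(CompoundRecord(id=cid, mol=mol))
    else:
        supplier = Chem.SDMolSupplier(str(structures_path), removeHs=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise ValueError(f"unparsable structure at SDF record {i}")
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") else f"cmpd-{i}"
            group = mol.GetProp("group") if mol.HasProp("group") else "unassigned"
            records.append(CompoundRecord(id=cid, mol=mol, group=group))
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate compound id: {rec.id!r}")
        seen.add(rec.id)

    acts = pd.read_csv(activities_path)
    required = {"compound_id", "endpoint", "value"}
    if not required <= set(acts.columns):
        raise ValueError(f"activity CSV must have columns {sorted(required)}")
    matched = acts["compound_id"].isin(seen)
    n_unmatched = int((~matched).sum())
    acts = acts[matched]
    table = acts.pivot_table(index="compound_id", columns="endpoint",
                             values="value", aggfunc="first")
    table = table.reindex([r.id for r in records])
    table.columns.name = None
    table.index.name = None
    if endpoints is not None:
        table = table.reindex(columns=list(endpoints))
    table.attrs["n_unmatched"] = n_unmatched
    return records, table


def neg_log_transform(raw, unit: str = "uM"):
    """pX = −log10 of a concentration, normalized to molar first.

    ``unit`` names the unit of the raw values (µM by default; use "ratio"
    for dimensionless relative potencies such as REC, which are used as-is).
    Nonpositive values are rejected with their positions.
    """
    if unit not in _UNIT_TO_MOLAR:
        raise ValueError(f"unknown unit {unit!r}; one of {sorted(_UNIT_TO_MOLAR)}")
    scalar = np.ndim(raw) == 0
    arr = np.atleast_1d(np.asarray(raw, dtype=float))
    bad = np.where(~(arr > 0))[0]
    if bad.size:
        raise ValueError(f"nonpositive concentration at positions {bad.tolist()}")
    out = -np.log10(arr * _UNIT_TO_MOLAR[unit])
    if scalar:
        return float(out[0])
    if isinstance(raw, pd.Series):
        return pd.Series(out, index=raw.index)
    return out


def assign_groups(records: list[CompoundRecord],
                  group_patterns: dict[str, str]) -> list[CompoundRecord]:
    """Label each record with the first matching skeleton pattern.

    ``group_patterns`` maps label → SMARTS; insertion order is the priority
    order, so a compound matching several skeletons gets the earliest label.
    Non-matching records keep/get the label "unassigned".
    """
    patterns = {}
    for label, smarts in group_patterns.items():
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"unparsable SMARTS for group {label!r}")
        patterns[label] = patt
    for rec in records:
        rec.group = "unassigned"
        for label, patt in patterns.items():
            if rec.mol.HasSubstructMatch(patt):
                rec.group = label
                break
    return records


def split_train_test(records: list[CompoundRecord], fraction: float = 0.8,
                     n_repeats: int = 5, seed: int = 0,
                     train_size: int | None = None,
                     n_bins: int = 10) -> list[SplitPlan]:
    """Molecular-weight-stratified random 80/20 splits, repeated.

    Compounds are sorted by molecular weight and cut into ``n_bins``
    weight bins; the training quota (round-half-even of fraction·n, or an
    explicit ``train_size`` override) is apportioned to the bins by largest
    remainder and sampled uniformly within each bin.  Each repeat uses an
    independent stream spawned from ``seed``.
    """
    n = len(records)
    if n < 5:
        raise ValueError("need at least 5 compounds to split")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    target = train_size if train_size is not None else int(np.rint(fraction * n))
    if not 0 < target < n:
        raise ValueError(f"training size {target} infeasible for n={n}")
    order = np.argsort([r.mol_weight for r in records], kind="stable")
    ids_sorted = [records[i].id for i in order]
    bins = np.array_split(np.arange(n), min(n_bins, n))
    quota_float = np.array([len(b) for b in bins]) * target / n
    quota = np.floor(quota_float).astype(int)
    remainder = target - quota.sum()
    frac_order = np.argsort(-(quota_float - quota), kind="stable")
    for j in frac_order[:remainder]:
        quota[j] += 1

    plans = []
    streams = np.random.SeedSequence(seed).spawn(n_repeats)
    for rep, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        train_idx = []
        for b, q in zip(bins, quota):
            q = min(q, len(b))
            train_idx.extend(rng.choice(b, size=q, replace=False))
        train_set = set(train_idx)
        train_ids = [ids_sorted[i] for i in sorted(train_set)]
        test_ids = [ids_sorted[i] for i in range(n) if i not in train_set]
        plans.append(SplitPlan(repeat=rep, train_ids=train_ids,
                               test_ids=test_ids, seed=seed))
    return plans


def split_plans_to_frame(plans: list[SplitPlan]) -> pd.DataFrame:
    rows = []
    for plan in plans:
        rows += [{"repeat": plan.repeat, "id": cid, "role": "train"}
                 for cid in plan.train_ids]
        rows += [{"repeat": plan.repeat, "id": cid, "role": "test"}
                 for cid in plan.test_ids]
    return pd.DataFrame(rows)


def write_split_plans(plans: list[SplitPlan], path) -> None:
    split_plans_to_frame(plans).to_csv(path, index=False)
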