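"""Hologram QSAR: fragment enumeration, hashing, and PLS over a scan grid.

Every connected induced subgraph of the heavy-atom graph with a size inside
a chosen atom-count window is a fragment.  Fragments are rendered as
canonical SMILES (element- and bond-order-aware; charge- and chirality-
agnostic by default), hashed with CRC-32 (the IEEE 802.3 polynomial
0xEDB88320 — fixed, portable and documented, unlike commercial hashes) and
folded modulo a hologram length from the canonical prime-length set.  A
PLS1 model is fit per (atom window, length) configuration and the
configuration with the best leave-one-out q² wins.

Enumeration uses the ESU (exact subgraph enumeration) scheme, which emits
each connected vertex set exactly once, so the total fragment count is the
number of connected induced subgraphs in the window, with multiplicity.
"""

from __future__ import annotations

import zlib
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .pls import PLS1Regression, loo_q2_pls, press_q2

__all__ = ["HOLOGRAM_LENGTHS", "enumerate_fragments", "build_hologram",
           "hologram_matrix", "HologramQSAR", "HQSARModel"]

#: canonical hologram lengths (primes; coprime to fragment-count patterns)
HOLOGRAM_LENGTHS = (53, 59, 61, 71, 83, 97, 151, 199, 257, 307, 353, 401)

DEFAULT_RANGES = ((4, 7), (1, 10))
MAX_FRAGMENT_ATOMS = 10


def _connected_subgraph_atom_sets(adj: list[int], n: int, max_size: int):
    """All connected vertex subsets of size ≤ max_size, each exactly once.

    ``adj[v]`` is a neighbor bitmask.  ESU: subsets are rooted at their
    minimum vertex; the extension set only ever contains vertices larger
    than the root that are not yet reachable through the current subset.
    """
    out = []

    def extend(sub_mask, sub_size, ext_mask, nbh_mask, root):
        out.append(sub_mask)
        if sub_size == max_size:
            return
        ext = ext_mask
        while ext:
            u = (ext & -ext).bit_length() - 1
            u_bit = 1 << u
            ext ^= u_bit
            new_nbh = nbh_mask | adj[u]
            # neighbors of u, above root, not already in subset/neighborhood
            add = adj[u] & ~nbh_mask & ~sub_mask & ~((1 << (root + 1)) - 1)
            extend(sub_mask | u_bit, sub_size + 1, ext | add, new_nbh, root)

    for v in range(n):
        above = ~((1 << (v + 1)) - 1)
        extend(1 << v, 1, adj[v] & above, adj[v] | (1 << v), v)
    return out


def enumerate_fragments(mol, min_atoms: int, max_atoms: int) -> Counter:
    """Multiset of canonical fragment strings over heavy atoms.

    Each connected induced subgraph with min_atoms ≤ size ≤ max_atoms
    contributes one canonical SMILES (multiplicity preserved).  Hydrogens do
    not count toward the size limits.  Disconnected molecules are handled
    per component (ESU never crosses components).
    """
    if not 1 <= min_atoms <= max_atoms <= MAX_FRAGMENT_ATOMS:
        raise ValueError(
            f"atom limits must satisfy 1 <= min <= max <= {MAX_FRAGMENT_ATOMS}")
    n = mol.GetNumAtoms()
    adj = [0] * n
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i] |= 1 << j
        adj[j] |= 1 << i
    frags: Counter = Counter()
    for mask in _connected_subgraph_atom_sets(adj, n, max_atoms):
        size = mask.bit_count()
        if size < min_atoms:
            continue
        atoms = [k for k in range(n) if mask >> k & 1]
        smi = Chem.MolFragmentToSmiles(mol, atomsToUse=atoms, canonical=True,
                                       isomericSmiles=False)
        frags[smi] += 1
    return frags


def _hash_fragment(s: str, hash_seed: int = 0) -> int:
    return zlib.crc32(s.encode("utf-8"), hash_seed & 0xFFFFFFFF)


def build_hologram(fragments, L: int, hash_seed: int = 0) -> np.ndarray:
    """Fold a fragment multiset into a length-L integer bin vector.

    bin(f) = CRC32(canonical string) mod L.  The total count is conserved:
    the bins sum to the fragment multiset size.
    """
    if L not in HOLOGRAM_LENGTHS:
        raise ValueError(f"hologram length {L} not in the allowed set "
                         f"{HOLOGRAM_LENGTHS}")
    h = np.zeros(L, dtype=np.int64)
    items = fragments.items() if isinstance(fragments, dict) else (
        (f, 1) for f in fragments)
    for s, c in items:
        h[_hash_fragment(s, hash_seed) % L] += c
    return h


def hologram_matrix(fragment_sets, L: int, hash_seed: int = 0) -> np.ndarray:
    return np.vstack([build_hologram(fs, L, hash_seed) for fs in fragment_sets])


@dataclass
class HQSARModel:
    length: int
    atom_range: tuple[int, int]
    n_components: int
    r2: float
    se_train: float
    q2: float
    se_loo: float
    train_mean: float
    pls: PLS1Regression = None


class HologramQSAR(RegressorMixin, BaseEstimator):
    """Hologram QSAR regressor with (atom window × length) model selection.

    Parameters
    ----------
    lengths : iterable of hologram lengths from :data:`HOLOGRAM_LENGTHS`.
    ranges : iterable of (min_atoms, max_atoms) fragment-size windows.
    max_components : PLS component cap; the count maximizing LOO q² is used.
    hash_seed : CRC-32 start value (fixed default keeps holograms portable).

    Fitted attributes
    -----------------
    best_ : the winning :class:`HQSARModel`.
    scan_ : DataFrame of (min_atoms, max_atoms, length, n_components, q²)
        for every scanned configuration.
    """

    def __init__(self, lengths=(53, 97, 151), ranges=DEFAULT_RANGES,
                 max_components: int = 6, hash_seed: int = 0):
        self.lengths = lengths
        self.ranges = ranges
        self.max_components = max_components
        self.hash_seed = hash_seed

    def fit(self, X, y):
        """Fit on a list of RDKit molecules X and activities y."""
        mols = list(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(mols) < 5:
            raise ValueError("need at least 5 compounds")
        for L in self.lengths:
            if L not in HOLOGRAM_LENGTHS:
                raise ValueError(f"length {L} not in {HOLOGRAM_LENGTHS}")
        # enumerate once per molecule at the widest window, keep per-size
        lo = min(r[0] for r in self.ranges)
        hi = max(r[1] for r in self.ranges)
        sized: list[dict] = []
        for mol in mols:
            per_size: dict[int, Counter] = {}
            for smi, c in enumerate_fragments(mol, lo, hi).items():
                size = Chem.MolFromSmiles(smi, sanitize=False).GetNumAtoms()
                per_size.setdefault(size, Counter())[smi] += c
            sized.append(per_size)

        rows = []
        best = None
        for rng in self.ranges:
            frag_sets = [
                sum((ps.get(s, Counter()) for s in range(rng[0], rng[1] + 1)),
                    Counter())
                for ps in sized]
            if all(sum(fs.values()) == 0 for fs in frag_sets):
                raise ValueError(
                    f"atom window {rng} excludes every substructure")
            for L in self.lengths:
                H = hologram_matrix(frag_sets, L, self.hash_seed)
                k, q2, se_loo, _ = loo_q2_pls(H, y, self.max_components)
                rows.append({"min_atoms": rng[0], "max_atoms": rng[1],
                             "length": L, "n_components": k, "q2": q2})
                if best is None or q2 > best[0]:
                    best = (q2, se_loo, rng, L, k, H, frag_sets)
        self.scan_ = pd.DataFrame(rows)

        q2, se_loo, rng, L, k, H, frag_sets = best
        pls = PLS1Regression(n_components=k).fit(H, y)
        fitted = pls.predict(H)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        rss = float(np.sum((y - fitted) ** 2))
        self.best_ = HQSARModel(
            length=L, atom_range=rng, n_components=pls.n_components_,
            r2=1.0 - rss / ss_tot,
            se_train=float(np.sqrt(rss / max(len(y) - pls.n_components_ - 1, 1))),
            q2=q2, se_loo=se_loo, train_mean=float(y.mean()), pls=pls)
        self.fitted_ = fitted
        return self

    def _holograms(self, mols) -> np.ndarray:
        rng = self.best_.atom_range
        return np.vstack([
            build_hologram(enumerate_fragments(m, rng[0], rng[1]),
                           self.best_.length, self.hash_seed)
            for m in mols])

    def predict(self, X):
        """Predict activities; a molecule with no fragments in the window
        falls back to the training mean."""
        check_is_fitted(self, "best_")
        H = self._holograms(list(X))
        pred = self.best_.pls.predict(H)
        empty = H.sum(axis=1) == 0
        pred[empty] = self.best_.train_mean
        return pred
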