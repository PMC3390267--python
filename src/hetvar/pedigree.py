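"""Pedigree handling: validation, inbreeding and the inverse numerator relationship matrix.

The animal models fitted by :mod:`hetvar.step1` and :mod:`hetvar.step2` assume
additive-genetic covariance proportional to the numerator relationship matrix
``A`` derived from the pedigree.  Only its sparse inverse is ever assembled into
the mixed-model equations; the dense tabular ``A`` is exposed for small
sub-pedigrees as a cross-checking device.

Unknown parents are coded with a single UNKNOWN token ("0" or empty in files);
unknown-parent groups are not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = "0"
_UNKNOWN_TOKENS = {"", "0", ".", "na", "nan", "none", "unknown"}

__all__ = [
    "UNKNOWN",
    "Pedigree",
    "RelationshipFactors",
    "PedigreeError",
    "load_pedigree",
    "read_pedigree",
    "write_pedigree",
    "inbreeding",
    "a_inverse",
    "relationship_submatrix",
]


class PedigreeError(ValueError):
    """Raised for structural pedigree defects (cycles, conflicting duplicates)."""


def _is_unknown(token) -> bool:
    if token is None:
        return True
    if isinstance(token, float) and np.isnan(token):
        return True
    return str(token).strip().lower() in _UNKNOWN_TOKENS


def _norm_sex(token) -> str:
    t = "" if token is None else str(token).strip().upper()
    if t in {"M", "MALE", "1"}:
        return "M"
    if t in {"F", "FEMALE", "2"}:
        return "F"
    return "U"


@dataclass
class Pedigree:
    """Topologically sorted pedigree with dense 0-based internal ids.

    ``sire`` / ``dam`` hold the internal index of the parent or −1 for unknown.
    External id tokens are preserved in ``ids``; ``index_of`` maps them back.
    Every known parent precedes its offspring.
    """

    ids: np.ndarray            # object array of external tokens, topological order
    sire: np.ndarray           # int array, -1 = unknown
    dam: np.ndarray            # int array, -1 = unknown
    sex: np.ndarray            # object array of {M, F, U}
    generation: np.ndarray     # int array; founders = 0
    n_added_founders: int = 0  # parents referenced but not listed, added silently
    index_of: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self.index_of:
            self.index_of = {t: i for i, t in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    def indices(self, tokens) -> np.ndarray:
        try:
            return np.array([self.index_of[str(t)] for t in tokens], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"animal id {exc.args[0]!r} not in pedigree") from None

    def progeny_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Number of offspring of each animal as sire and as dam."""
        as_sire = np.bincount(self.sire[self.sire >= 0], minlength=self.n)
        as_dam = np.bincount(self.dam[self.dam >= 0], minlength=self.n)
        return as_sire, as_dam

    def to_frame(self) -> pd.DataFrame:
        def tok(ix):
            return np.where(ix >= 0, self.ids[np.maximum(ix, 0)], UNKNOWN)

        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": tok(self.sire),
                "dam": tok(self.dam),
                "sex": self.sex,
                "generation": self.generation,
            }
        )


def load_pedigree(records) -> Pedigree:
    """Build a validated, topologically sorted pedigree from raw records.

    Parameters
    ----------
    records
        Iterable of (animal, sire, dam) or (animal, sire, dam, sex) tuples of
        tokens.  Unknown parents may be coded as "0", "", "." or None.

    Unlisted parents are appended as founders (counted in
    ``n_added_founders``, with a warning).  Exact duplicate records collapse;
    duplicates with conflicting parents raise :class:`PedigreeError`, as do
    ancestry cycles.
    """
    raw: dict[str, tuple[str | None, str | None, str]] = {}
    order: list[str] = []
    for rec in records:
        rec = tuple(rec)
        animal = str(rec[0]).strip()
        if not animal or _is_unknown(animal):
            raise PedigreeError("animal id must be a non-empty token")
        s = None if _is_unknown(rec[1]) else str(rec[1]).strip()
        d = None if _is_unknown(rec[2]) else str(rec[2]).strip()
        sx = _norm_sex(rec[3]) if len(rec) > 3 else "U"
        if animal in raw:
            ps, pd_, psx = raw[animal]
            if (ps, pd_) != (s, d):
                raise PedigreeError(
                    f"duplicate animal {animal!r} with conflicting parents"
                )
            if psx == "U" and sx != "U":
                raw[animal] = (ps, pd_, sx)
            continue
        raw[animal] = (s, d, sx)
        order.append(animal)

    n_added = 0
    for animal in list(order):
        s, d, _ = raw[animal]
        for p, psex in ((s, "M"), (d, "F")):
            if p is not None and p not in raw:
                raw[p] = (None, None, psex)
                order.append(p)
                n_added += 1
        if s is not None and raw[s][2] == "U":
            raw[s] = (raw[s][0], raw[s][1], "M")
        if d is not None and raw[d][2] == "U":
            raw[d] = (raw[d][0], raw[d][1], "F")
    if n_added:
        warnings.warn(
            f"{n_added} parent(s) not listed as animals; added as founders",
            stacklevel=2,
        )

    # Kahn topological sort by parent links; stable w.r.t. input order.
    children: dict[str, list[str]] = {a: [] for a in order}
    missing_parents = {}
    for a in order:
        s, d, _ = raw[a]
        np_ = 0
        for p in (s, d):
            if p is not None:
                children[p].append(a)
                np_ += 1
        missing_parents[a] = np_
    from collections import deque

    queue = deque(a for a in order if missing_parents[a] == 0)
    sorted_ids: list[str] = []
    gen: dict[str, int] = {}
    while queue:
        a = queue.popleft()
        s, d, _ = raw[a]
        gen[a] = max(
            (gen[p] + 1 for p in (s, d) if p is not None), default=0
        )
        sorted_ids.append(a)
        for c in children[a]:
            missing_parents[c] -= 1
            if missing_parents[c] == 0:
                queue.append(c)
    if len(sorted_ids) < len(order):
        on_cycle = next(a for a in order if missing_parents[a] > 0)
        raise PedigreeError(f"pedigree contains an ancestry cycle involving {on_cycle!r}")

    index = {a: i for i, a in enumerate(sorted_ids)}
    n = len(sorted_ids)
    sire = np.full(n, -1, dtype=np.int64)
    dam = np.full(n, -1, dtype=np.int64)
    sex = np.empty(n, dtype=object)
    generation = np.zeros(n, dtype=np.int64)
    for a, i in index.items():
        s, d, sx = raw[a]
        if s is not None:
            sire[i] = index[s]
        if d is not None:
            dam[i] = index[d]
        sex[i] = sx
        generation[i] = gen[a]

    return Pedigree(
        ids=np.array(sorted_ids, dtype=object),
        sire=sire,
        dam=dam,
        sex=sex,
        generation=generation,
        n_added_founders=n_added,
        index_of=index,
    )


def read_pedigree(path) -> Pedigree:
    """Read a delimited pedigree file with header animal,sire,dam[,sex]."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    need = ["animal", "sire", "dam"]
    if any(c not in cols for c in need):
        raise PedigreeError(f"pedigree file must have columns {need}, got {cols}")
    fields = need + (["sex"] if "sex" in cols else [])
    return load_pedigree(df[fields].itertuples(index=False, name=None))


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().drop(columns="generation").to_csv(path, index=False)


@dataclass
class RelationshipFactors:
    """Per-animal inbreeding F and Mendelian-sampling diagonal d.

    ``d[i] = 0.5 − 0.25 (F_s + F_d)`` for two known parents, 0.75 for one,
    1.0 for founders; these are the diagonal elements of the D matrix in
    ``A = L D L'`` and drive both Henderson's A-inverse rules and the
    Mendelian-sampling variance used by the simulator.
    """

    inbreeding: np.ndarray
    mendelian_diag: np.ndarray

    @property
    def log_det_A(self) -> float:
        """log |A| = Σ log d_i (from A = L D L' with unit-diagonal L)."""
        return float(np.sum(np.log(self.mendelian_diag)))


def inbreeding(ped: Pedigree) -> RelationshipFactors:
    """Exact inbreeding coefficients via the Meuwissen–Luo recursion.

    Processes animals in topological order, accumulating for each animal the
    row of L (ancestor contributions) with the D diagonal; F_i = Σ_j L_ij² d_j − 1
    ... computed family-wise so the cost stays proportional to the number of
    ancestor paths, which is small for shallow simulated pedigrees.
    """
    n = ped.n
    F = np.zeros(n)
    d = np.ones(n)
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, di = sire[i], dam[i]
        if s < 0 and di < 0:
            F[i] = 0.0
            d[i] = 1.0
            continue
        if s < 0 or di < 0:
            F[i] = 0.0
            d[i] = 0.75
        else:
            d[i] = 0.5 - 0.25 * (F[s] + F[di])
            if s == di:
                F[i] = 0.5 * (1.0 + F[s])
            else:
                # F_i = A_{s,d} / 2; accumulate L-row contributions of s and d
                # over their common ancestors.
                F[i] = 0.5 * _relationship_pair(sire, dam, d, s, di)
    return RelationshipFactors(inbreeding=F, mendelian_diag=d)


def _relationship_pair(sire, dam, d, a, b) -> float:
    """A_{a,b} for a != b using L-row expansion: A_ab = Σ_k L_ak L_bk d_k."""
    La: dict[int, float] = {}
    Lb: dict[int, float] = {}
    _l_row(sire, dam, a, La)
    _l_row(sire, dam, b, Lb)
    if len(La) > len(Lb):
        La, Lb = Lb, La
    return sum(v * Lb[k] * d[k] for k, v in La.items() if k in Lb)


def _l_row(sire, dam, i, out: dict[int, float]) -> None:
    """Accumulate row i of L (coefficients on Mendelian terms of ancestors)."""
    stack = [(i, 1.0)]
    while stack:
        k, w = stack.pop()
        out[k] = out.get(k, 0.0) + w
        if sire[k] >= 0:
            stack.append((sire[k], 0.5 * w))
        if dam[k] >= 0:
            stack.append((dam[k], 0.5 * w))


def a_inverse(ped: Pedigree, factors: RelationshipFactors | None = None) -> sp.csr_matrix:
    """Sparse inverse of the numerator relationship matrix (Henderson's rules).

    For each animal i with Mendelian variance d_i and parents p ∈ {s, d}:
    add 1/d_i at (i,i), −0.5/d_i at (i,p) and (p,i), 0.25/d_i at (p,p').
    """
    if factors is None:
        factors = inbreeding(ped)
    n = ped.n
    alpha = 1.0 / factors.mendelian_diag
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    idx = np.arange(n)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    add(idx, idx, alpha)
    for parent in (ped.sire, ped.dam):
        m = parent >= 0
        add(idx[m], parent[m], -0.5 * alpha[m])
        add(parent[m], idx[m], -0.5 * alpha[m])
    for pa in (ped.sire, ped.dam):
        for pb in (ped.sire, ped.dam):
            m = (pa >= 0) & (pb >= 0)
            add(pa[m], pb[m], 0.25 * alpha[m])
    A_inv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    A_inv.sum_duplicates()
    return A_inv


def relationship_submatrix(ped: Pedigree, ids) -> np.ndarray:
    """Dense tabular-method A restricted to ``ids`` (diagonal = 1 + F).

    Computes the full recurrence A_ij = 0.5 (A_{i,s(j)} + A_{i,d(j)}) over the
    ancestor closure of the requested animals, so it is intended for
    small-to-moderate sub-pedigrees (cross-checks, EBV validation).
    """
    want = ped.indices(ids) if not isinstance(ids, np.ndarray) or ids.dtype != np.int64 else ids
    want = np.asarray(want, dtype=np.int64)
    # ancestor closure
    needed = np.zeros(ped.n, dtype=bool)
    stack = list(want)
    while stack:
        k = stack.pop()
        if needed[k]:
            continue
        needed[k] = True
        for p in (ped.sire[k], ped.dam[k]):
            if p >= 0 and not needed[p]:
                stack.append(p)
    sub = np.flatnonzero(needed)  # ascending == topological
    pos = -np.ones(ped.n, dtype=np.int64)
    pos[sub] = np.arange(len(sub))
    m = len(sub)
    A = np.zeros((m, m))
    for jj, j in enumerate(sub):
        s = pos[ped.sire[j]] if ped.sire[j] >= 0 else -1
        dm = pos[ped.dam[j]] if ped.dam[j] >= 0 else -1
        if jj:
            prev = slice(0, jj)
            row = np.zeros(jj)
            if s >= 0:
                row += 0.5 * A[prev, s]
            if dm >= 0:
                row += 0.5 * A[prev, dm]
            A[prev, jj] = row
            A[jj, prev] = row
        diag = 1.0
        if s >= 0 and dm >= 0:
            diag += 0.5 * A[s, dm]
        A[jj, jj] = diag
    return A[np.ix_(pos[want], pos[want])]
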