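"""Association networks from scan-sampled party data.

Scan sampling records, at regular intervals, which individuals of a group
are associating (here: party co-membership, the transitive closure of the
field rule "within one body length").  From those records this module builds
the simple ratio index (SRI) network

    a_ij = x_ij / (x_ij + y_ij)

where ``x_ij`` counts scans in which *i* and *j* shared a party and ``y_ij``
counts scans in which both were present but in different parties.  The SRI
matrix is the weighted "social network" the diffusion analysis runs on; a
"group network" with every off-diagonal entry set to 1 is the homogeneous
null against which network structure is tested.

Diagnostics: the social differentiation coefficient (sd/mean of the dyadic
indices, a coefficient of variation measuring how heterogeneous the
associations are) and a seeded Mantel matrix-permutation test for comparing
two networks over their shared individuals.
"""
from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConsistencyError,
    DegenerateNetworkError,
    IdentityError,
    InputError,
    InsufficientOverlapError,
    UndefinedCoefficientError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Individual",
    "Scan",
    "ScanDataset",
    "AssociationNetwork",
    "MantelResult",
    "read_roster",
    "read_scan_samples",
    "compute_sri_network",
    "social_differentiation",
    "mantel_test",
    "homogeneous_network",
]


@dataclass(frozen=True)
class Individual:
    """One study animal.

    Sex is coded numerically (female = 1, male = 0) and age in decimal
    years, with pups under one year expressed as a fraction (a
    three-month-old has ``age = 0.25``).  ``age_by_round`` optionally holds
    round-specific ages for studies whose rounds are months apart.
    """

    id: str
    group: str
    sex: int
    age: float
    age_by_round: dict[int, float] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise InputError(f"individual {self.id!r}: sex must be 0 or 1, got {self.sex!r}")
        if not self.age > 0:
            raise InputError(f"individual {self.id!r}: age must be positive, got {self.age!r}")

    def age_at(self, round_: int) -> float:
        return self.age_by_round.get(round_, self.age)


@dataclass(frozen=True)
class Scan:
    """One scan sample: a partition of the present individuals into parties."""

    session: str
    scan_index: int
    parties: tuple[frozenset[str], ...]

    @property
    def present(self) -> frozenset[str]:
        return frozenset(itertools.chain.from_iterable(self.parties))


@dataclass
class ScanDataset:
    """Ordered scan samples for one group plus its roster."""

    group: str
    scans: list[Scan]
    roster: list[Individual]

    def __post_init__(self) -> None:
        if not self.scans:
            raise InputError(f"group {self.group!r}: scan dataset is empty")
        ids = {ind.id for ind in self.roster}
        if len(ids) != len(self.roster):
            raise ConsistencyError(f"group {self.group!r}: duplicate ids in roster")
        for scan in self.scans:
            seen: set[str] = set()
            for party in scan.parties:
                dup = seen & party
                if dup:
                    raise ConsistencyError(
                        f"scan {scan.session}/{scan.scan_index}: individual(s) "
                        f"{sorted(dup)} appear in more than one party"
                    )
                seen |= party
            unknown = seen - ids
            if unknown:
                raise IdentityError(
                    f"scan {scan.session}/{scan.scan_index}: unknown individual(s) "
                    f"{sorted(unknown)} not in roster"
                )

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(ind.id for ind in self.roster)


@dataclass
class AssociationNetwork:
    """A symmetric dyadic index matrix over an ordered roster.

    ``kind`` is ``"social"`` for an SRI network and ``"group"`` for the
    homogeneous all-ones null network.  Networks are immutable snapshots;
    ``label`` can tag the presentation round they belong to.
    """

    ids: tuple[str, ...]
    matrix: np.ndarray
    kind: str = "social"
    label: str = ""
    n_scans: int | None = None

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        m = np.array(self.matrix, dtype=float, copy=True)
        if m.shape != (len(self.ids), len(self.ids)):
            raise InputError("matrix shape does not match roster length")
        if not np.allclose(m, m.T):
            raise InputError("association matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise InputError("association matrix diagonal must be zero")
        off = m[~np.eye(len(self.ids), dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1):
            raise InputError("association indices must lie in [0, 1]")
        if self.kind not in ("social", "group"):
            raise InputError(f"kind must be 'social' or 'group', got {self.kind!r}")
        if self.kind == "group" and off.size and not np.all(off == 1.0):
            raise InputError("group network requires every off-diagonal entry equal to 1")
        m.flags.writeable = False
        self.matrix = m

    @property
    def n(self) -> int:
        return len(self.ids)

    def dyad_indices(self) -> np.ndarray:
        """Upper-triangle dyadic indices as a flat vector."""
        iu = np.triu_indices(self.n, k=1)
        return self.matrix[iu]

    def subnetwork(self, ids: Sequence[str]) -> "AssociationNetwork":
        pos = [self.ids.index(i) for i in ids]
        sub = self.matrix[np.ix_(pos, pos)].copy()
        return AssociationNetwork(tuple(ids), sub, kind=self.kind, label=self.label,
                                  n_scans=self.n_scans)

    def to_csv(self, path: str | Path) -> None:
        """Write the matrix as labelled CSV with a JSON sidecar of metadata."""
        path = Path(path)
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(path)
        meta = {"kind": self.kind, "label": self.label, "n_scans": self.n_scans}
        try:
            meta["social_differentiation"] = social_differentiation(self)
        except UndefinedCoefficientError:
            meta["social_differentiation"] = None
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "AssociationNetwork":
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        kind, label, n_scans = "social", "", None
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            kind = meta.get("kind", "social")
            label = meta.get("label", "")
            n_scans = meta.get("n_scans")
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float),
                   kind=kind, label=label, n_scans=n_scans)


@dataclass(frozen=True)
class MantelResult:
    """Mantel matrix correlation with a one-sided permutation p-value."""

    r_m: float
    p: float
    n_perm: int
    seed: int


def read_roster(path: str | Path) -> list[Individual]:
    """Read a roster CSV: ``individual_id,group,sex,age_years``.

    Sex is given as ``F``/``M`` and mapped to 1/0.  Optional columns
    ``age_years_r1``, ``age_years_r2``, ... provide round-specific ages.
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "group": str})
    if df.empty:
        raise InputError(f"roster file {path} contains no rows")
    required = {"individual_id", "group", "sex"}
    if not required <= set(df.columns):
        raise InputError(f"roster file {path} missing columns {sorted(required - set(df.columns))}")
    round_cols = sorted(c for c in df.columns if c.startswith("age_years_r"))
    if "age_years" not in df.columns and not round_cols:
        raise InputError(f"roster file {path} has no age column")
    sex_map = {"F": 1, "M": 0, "1": 1, "0": 0, 1: 1, 0: 0}
    out: list[Individual] = []
    for _, row in df.iterrows():
        sex_raw = row["sex"]
        key = sex_raw.strip().upper() if isinstance(sex_raw, str) else sex_raw
        if key not in sex_map:
            raise InputError(f"roster: unrecognised sex code {sex_raw!r}")
        by_round = {int(c.rsplit("r", 1)[1]): float(row[c]) for c in round_cols
                    if pd.notna(row[c])}
        age = float(row["age_years"]) if "age_years" in df.columns else by_round[min(by_round)]
        out.append(Individual(id=str(row["individual_id"]), group=str(row["group"]),
                              sex=int(sex_map[key]), age=age, age_by_round=by_round))
    return out


def read_scan_samples(path: str | Path, roster_path: str | Path,
                      group: str | None = None) -> ScanDataset:
    """Read long-format scan CSV (``group,session,scan_index,individual_id,party_id``)
    together with its roster, returning a validated :class:`ScanDataset`.

    If the file holds several groups, ``group`` selects one.
    """
    roster = read_roster(roster_path)
    df = pd.read_csv(path, dtype={"group": str, "session": str, "individual_id": str,
                                  "party_id": str})
    if df.empty:
        raise InputError(f"scan file {path} contains no rows")
    groups = df["group"].unique()
    if group is None:
        if len(groups) > 1:
            raise InputError(f"scan file holds groups {sorted(groups)}; pass group=")
        group = groups[0]
    df = df[df["group"] == group]
    if df.empty:
        raise InputError(f"scan file has no rows for group {group!r}")
    roster = [ind for ind in roster if ind.group == group]
    scans: list[Scan] = []
    for (session, idx), block in df.groupby(["session", "scan_index"], sort=False):
        parties = tuple(frozenset(sub["individual_id"])
                        for _, sub in block.groupby("party_id", sort=True))
        scans.append(Scan(session=str(session), scan_index=int(idx), parties=parties))
    return ScanDataset(group=group, scans=scans, roster=roster)


def compute_sri_network(scans: ScanDataset, label: str = "") -> AssociationNetwork:
    """Simple ratio index network from scan samples.

    For each dyad, the number of scans spent in the same party divided by
    the number of scans in which both were present.  Dyads never co-present
    get index 0 with a logged warning so the matrix stays complete.
    """
    ids = scans.ids
    n = len(ids)
    pos = {i: k for k, i in enumerate(ids)}
    together = np.zeros((n, n))
    copresent = np.zeros((n, n))
    for scan in scans.scans:
        present = [pos[i] for i in scan.present]
        pv = np.zeros(n, dtype=bool)
        pv[present] = True
        copresent += np.outer(pv, pv)
        for party in scan.parties:
            members = [pos[i] for i in party]
            mv = np.zeros(n, dtype=bool)
            mv[members] = True
            together += np.outer(mv, mv)
    with np.errstate(invalid="ignore", divide="ignore"):
        sri = np.where(copresent > 0, together / np.maximum(copresent, 1), 0.0)
    np.fill_diagonal(sri, 0.0)
    never = [(ids[i], ids[j]) for i, j in zip(*np.triu_indices(n, k=1))
             if copresent[i, j] == 0]
    if never:
        logger.warning("group %s: %d dyad(s) never co-present; SRI set to 0: %s",
                       scans.group, len(never), never[:5])
    return AssociationNetwork(ids, sri, kind="social", label=label,
                              n_scans=len(scans.scans))


def social_differentiation(net: AssociationNetwork, sample_sd: bool = True) -> float:
    """sd/mean of the dyadic association indices (coefficient of variation).

    Sample (n-1) standard deviation by default; ``sample_sd=False`` uses the
    population form.
    """
    dyads = net.dyad_indices()
    if dyads.size < 2:
        raise UndefinedCoefficientError("need at least two dyads")
    mean = dyads.mean()
    if mean == 0:
        raise UndefinedCoefficientError("mean association index is zero")
    return float(dyads.std(ddof=1 if sample_sd else 0) / mean)


def _offdiag_vector(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel_test(net_a: AssociationNetwork, net_b: AssociationNetwork,
                n_perm: int = 9999, seed: int = 0) -> MantelResult:
    """Mantel matrix-permutation test between two association networks.

    Restricted to the shared individuals; the correlation is the Pearson
    correlation of the off-diagonal dyad vectors, and the one-sided
    (greater) p-value comes from ``n_perm`` simultaneous row/column label
    permutations of the second matrix, with the +1 correction
    ``p = (#{r_perm >= r_obs} + 1) / (n_perm + 1)``.
    """
    shared = [i for i in net_a.ids if i in net_b.ids]
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared individual(s); need at least 3")
    a = net_a.subnetwork(shared).matrix
    b = net_b.subnetwork(shared).matrix
    va = _offdiag_vector(a)
    va = va - va.mean()
    sa = np.sqrt((va ** 2).sum())

    def corr_with(bm: np.ndarray) -> float:
        vb = _offdiag_vector(bm)
        vb = vb - vb.mean()
        sb = np.sqrt((vb ** 2).sum())
        if sa == 0 or sb == 0:
            return 0.0
        return float((va * vb).sum() / (sa * sb))

    r_obs = corr_with(b)
    rng = np.random.default_rng(seed)
    n = len(shared)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr_with(b[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r_m=r_obs, p=p, n_perm=n_perm, seed=seed)


def homogeneous_network(roster: Iterable[Individual] | Sequence[str],
                        label: str = "") -> AssociationNetwork:
    """All-ones "group network": the homogeneous-diffusion null."""
    ids = tuple(ind.id if isinstance(ind, Individual) else str(ind) for ind in roster)
    if len(ids) < 2:
        raise DegenerateNetworkError("homogeneous network needs at least 2 individuals")
    m = np.ones((len(ids), len(ids)))
    np.fill_diagonal(m, 0.0)
    return AssociationNetwork(ids, m, kind="group", label=label)
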