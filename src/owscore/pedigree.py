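"""Pedigree representation, validation, and kinship-derived relationship matrices.

A :class:`Pedigree` holds the members of a single family, topologically
ordered founders-first.  Kinship coefficients are computed by the standard
recursion over that order; :func:`phi_blocks` assembles the per-family
expected-relationship matrices ``Phi_i = 2 * kinship`` that enter the
denominator of the pedigree score statistics.

Founders are assumed mutually unrelated and non-inbred.  Inbreeding created
*within* the recorded pedigree (marriage loops) is handled correctly by the
recursion.  The sex field is carried through but unused: this is an autosomal
model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIndividualError,
    PedigreeCycleError,
    PedigreeOrderError,
    SingleParentError,
    UnknownParentError,
)

logger = logging.getLogger(__name__)

MISSING_PARENT = "0"

_SEX_CODES = {"1": "male", "2": "female", "m": "male", "f": "female",
              "male": "male", "female": "female"}


@dataclass(frozen=True)
class Member:
    """One pedigree member record (FAM-style)."""

    family_id: str
    individual_id: str
    father_id: str | None  # None for founders
    mother_id: str | None
    sex: str = "unknown"  # {male, female, unknown}; carried, not used

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """A validated single-family pedigree, members topologically ordered.

    The ordering invariant (every parent precedes its children) is what the
    kinship recursion relies on; :func:`validate_pedigree` establishes it.
    """

    family_id: str
    members: list[Member] = field(default_factory=list)

    @property
    def ids(self) -> list[str]:
        return [m.individual_id for m in self.members]

    @property
    def founders(self) -> list[Member]:
        return [m for m in self.members if m.is_founder]

    @property
    def nonfounders(self) -> list[Member]:
        return [m for m in self.members if not m.is_founder]

    def __len__(self) -> int:
        return len(self.members)


def _normalize_parent(pid: object) -> str | None:
    if pid is None:
        return None
    s = str(pid).strip()
    if s in ("", MISSING_PARENT, "NA", "nan"):
        return None
    return s


def _normalize_sex(sex: object) -> str:
    return _SEX_CODES.get(str(sex).strip().lower(), "unknown")


def validate_pedigree(raw_rows: Iterable[Sequence]) -> Pedigree:
    """Validate raw member records for one family and return a Pedigree.

    Each row is ``(family_id, individual_id, father_id, mother_id[, sex])``
    with ``"0"``/empty/``None`` denoting a missing parent.  Individuals named
    as parents but lacking their own record are auto-inserted as founders
    (with a logged warning), a common FAM-file dialect.

    Raises
    ------
    DuplicateIndividualError, SingleParentError, UnknownParentError,
    PedigreeCycleError
        One distinct error per invariant violation.
    ValueError
        If the rows span more than one family (use :func:`validate_pedigrees`).
    """
    rows = list(raw_rows)
    if not rows:
        raise ValueError("empty pedigree record set")

    fam_ids = {str(r[0]) for r in rows}
    if len(fam_ids) != 1:
        raise ValueError(f"rows span multiple families: {sorted(fam_ids)}")
    family_id = fam_ids.pop()

    records: dict[str, Member] = {}
    order: list[str] = []
    for r in rows:
        iid = str(r[1]).strip()
        father = _normalize_parent(r[2])
        mother = _normalize_parent(r[3])
        sex = _normalize_sex(r[4]) if len(r) > 4 else "unknown"
        if iid in records:
            raise DuplicateIndividualError(
                f"individual '{iid}' appears more than once in family '{family_id}'"
            )
        if (father is None) != (mother is None):
            raise SingleParentError(
                f"individual '{iid}' records exactly one parent; "
                "founders have zero parents, non-founders two"
            )
        if iid in (father, mother):
            raise PedigreeCycleError(f"individual '{iid}' is its own parent")
        records[iid] = Member(family_id, iid, father, mother, sex)
        order.append(iid)

    # Auto-insert parents that appear only as references (FAM dialect).
    for m in list(records.values()):
        for pid in (m.father_id, m.mother_id):
            if pid is not None and pid not in records:
                logger.warning(
                    "family %s: parent '%s' has no record; inserted as founder",
                    family_id, pid,
                )
                records[pid] = Member(family_id, pid, None, None, "unknown")
                order.insert(0, pid)

    for m in records.values():
        for pid in (m.father_id, m.mother_id):
            if pid is not None and pid not in records:
                raise UnknownParentError(
                    f"individual '{m.individual_id}' references unknown parent '{pid}'"
                )

    # Kahn topological sort by repeated founder-stripping; the frontier is a
    # heap keyed by input position, so ties break by input order and an input
    # that is already topologically sorted keeps its order exactly.
    import heapq

    position = {iid: k for k, iid in enumerate(order)}
    children: dict[str, list[str]] = {iid: [] for iid in records}
    remaining = {}
    for iid in order:
        m = records[iid]
        remaining[iid] = sum(p is not None for p in (m.father_id, m.mother_id))
        for pid in {m.father_id, m.mother_id} - {None}:
            children[pid].append(iid)

    sorted_ids: list[str] = []
    frontier = [position[iid] for iid in order if remaining[iid] == 0]
    heapq.heapify(frontier)
    while frontier:
        iid = order[heapq.heappop(frontier)]
        sorted_ids.append(iid)
        for child in children[iid]:
            remaining[child] -= 1
            if remaining[child] == 0:
                heapq.heappush(frontier, position[child])
    if len(sorted_ids) != len(records):
        cyclic = sorted(set(records) - set(sorted_ids))
        raise PedigreeCycleError(
            f"family '{family_id}': parent graph has a cycle involving {cyclic}"
        )

    return Pedigree(family_id, [records[iid] for iid in sorted_ids])


def validate_pedigrees(raw_rows: Iterable[Sequence]) -> list[Pedigree]:
    """Split raw rows by family ID and validate each family.

    Family order follows first appearance in the input.
    """
    by_family: dict[str, list[Sequence]] = {}
    for r in raw_rows:
        by_family.setdefault(str(r[0]), []).append(r)
    return [validate_pedigree(rows) for rows in by_family.values()]


def read_fam(path) -> list[Pedigree]:
    """Read a whitespace/tab-delimited FAM-style pedigree file.

    Columns: family_id, individual_id, father_id, mother_id, sex; a header
    line is auto-detected (first field equal to 'family_id'/'fid', case
    insensitive).  "0" denotes a missing parent.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    first = str(df.iloc[0, 0]).lower()
    if first in ("family_id", "fid", "famid", "fam"):
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] < 4:
        raise ValueError(f"{path}: expected >=4 pedigree columns, got {df.shape[1]}")
    return validate_pedigrees(df.itertuples(index=False))


def kinship_matrix(ped: Pedigree) -> np.ndarray:
    """Kinship coefficients phi for all member pairs by the standard recursion.

    Founders: phi(a,a) = 1/2, phi(a,b) = 0 for distinct founders.  A
    non-founder c with parents p, q satisfies phi(c,b) = (phi(p,b)+phi(q,b))/2
    for b != c and phi(c,c) = 1/2 + phi(p,q)/2, which accounts for inbreeding
    arising within the pedigree.  Requires the founders-first ordering that
    :func:`validate_pedigree` guarantees.
    """
    ids = ped.ids
    index = {iid: k for k, iid in enumerate(ids)}
    n = len(ids)
    phi = np.zeros((n, n))
    for k, m in enumerate(ped.members):
        if m.is_founder:
            phi[k, k] = 0.5
            continue
        p = index.get(m.father_id)
        q = index.get(m.mother_id)
        if p is None or q is None or p >= k or q >= k:
            raise PedigreeOrderError(
                f"family '{ped.family_id}': parent of '{m.individual_id}' "
                "appears after the child; pedigree not topologically ordered"
            )
        row = 0.5 * (phi[p, :k] + phi[q, :k])
        phi[k, :k] = row
        phi[:k, k] = row
        phi[k, k] = 0.5 + 0.5 * phi[p, q]
    return phi


@dataclass
class KinshipBlocks:
    """Per-family expected relationship matrices Phi_i = 2 * kinship.

    ``blocks[i]`` is square symmetric PSD with diagonal 1 + inbreeding
    coefficient; ``member_order[i]`` gives the individual ordering.  The study
    relationship matrix is block-diagonal over families (unrelated founders
    across families).
    """

    blocks: list[np.ndarray]
    member_order: list[list[str]]

    @property
    def sample_ids(self) -> list[str]:
        return [iid for ids in self.member_order for iid in ids]

    @property
    def n_samples(self) -> int:
        return sum(len(ids) for ids in self.member_order)

    def full_matrix(self) -> np.ndarray:
        """Dense block-diagonal Phi over the whole study."""
        from scipy.linalg import block_diag

        return block_diag(*self.blocks) if self.blocks else np.zeros((0, 0))

    def subset(self, keep_ids: Sequence[str]) -> "KinshipBlocks":
        """Restrict blocks to the given individuals, preserving block order.

        Marginalizing a relationship matrix is a plain row/column subset, so
        entries are unchanged; families left empty are dropped.
        """
        keep = set(keep_ids)
        blocks, orders = [], []
        for blk, ids in zip(self.blocks, self.member_order):
            mask = [k for k, iid in enumerate(ids) if iid in keep]
            if mask:
                blocks.append(blk[np.ix_(mask, mask)])
                orders.append([ids[k] for k in mask])
        return KinshipBlocks(blocks, orders)


def phi_blocks(ped_set: Sequence[Pedigree]) -> KinshipBlocks:
    """Compute Phi_i = 2 * kinship for each family of the study.

    A singleton individual yields the 1x1 block [1.0].
    """
    blocks = [2.0 * kinship_matrix(ped) for ped in ped_set]
    return KinshipBlocks(blocks, [ped.ids for ped in ped_set])
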