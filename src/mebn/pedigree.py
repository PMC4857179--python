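"""Pedigrees, additive genetic relationship matrices, and gene-dropped genotypes.

Family-based studies induce correlation between relatives: a quantitative
trait with genetic variance :math:`\\gamma^2` has covariance
:math:`2 k_{ij} \\gamma^2` between individuals *i* and *j* with kinship
coefficient :math:`k_{ij}`.  This module represents pedigrees, computes the
additive relationship matrix :math:`A = 2K` exactly by the standard tabular
recursion, builds synthetic multi-family cohorts, and simulates Mendelian
transmission of SNP alleles down a pedigree ("gene dropping").

The additive relationship matrix is block diagonal by family; all downstream
code (likelihoods, simulators) exploits that block structure.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "KinshipMatrix",
    "GenotypeMatrix",
    "kinship_from_pedigree",
    "make_synthetic_cohort",
    "gene_drop_snps",
    "read_ped",
    "write_ped",
    "FAMILY_TEMPLATES",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (missing parent, cycle, ...)."""


@dataclasses.dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father``/``mother`` are individual ids within the same family, or
    ``None`` for founders.  ``sampled`` distinguishes phenotyped study
    subjects from connecting ancestors that appear only to define
    relationships (e.g. deceased parents of a sibship).
    """

    iid: str
    fid: str
    father: str | None = None
    mother: str | None = None
    sex: int = 0
    sampled: bool = True


class Pedigree:
    """A collection of individuals partitioned into families.

    Invariants enforced on construction: ids are unique within a family,
    both parents of a non-founder exist in the same family (no cross-family
    parentage), and the parentage graph is acyclic.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: list[Individual] = list(individuals)
        self._index: dict[tuple[str, str], int] = {}
        for k, ind in enumerate(self.individuals):
            key = (ind.fid, ind.iid)
            if key in self._index:
                raise PedigreeError(f"duplicate individual {ind.iid!r} in family {ind.fid!r}")
            self._index[key] = k
        self._validate()

    def _validate(self) -> None:
        for ind in self.individuals:
            if (ind.father is None) != (ind.mother is None):
                raise PedigreeError(
                    f"individual {ind.iid!r} in family {ind.fid!r} has exactly one known parent"
                )
            for parent in (ind.father, ind.mother):
                if parent is not None and (ind.fid, parent) not in self._index:
                    raise PedigreeError(
                        f"individual {ind.iid!r} in family {ind.fid!r} references "
                        f"missing parent {parent!r}"
                    )
        self.topological()  # raises on cycles

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, key: tuple[str, str]) -> Individual:
        return self.individuals[self._index[key]]

    @property
    def families(self) -> list[str]:
        """Family ids in order of first appearance."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.fid, None)
        return list(seen)

    def members(self, fid: str) -> list[Individual]:
        return [ind for ind in self.individuals if ind.fid == fid]

    @property
    def sampled(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.sampled]

    def topological(self) -> list[int]:
        """Indices of all individuals with parents before children."""
        depth = self._depths()
        return sorted(range(len(self.individuals)), key=lambda k: (depth[k], k))

    def _depths(self) -> list[int]:
        memo: dict[int, int] = {}

        def depth(k: int) -> int:
            if k in memo:
                return memo[k]
            memo[k] = -1  # visiting marker
            ind = self.individuals[k]
            if ind.father is None:
                d = 0
            else:
                fi = self._index[(ind.fid, ind.father)]
                mi = self._index[(ind.fid, ind.mother)]
                for p in (fi, mi):
                    if memo.get(p) == -1:
                        raise PedigreeError(f"parentage cycle involving {ind.iid!r}")
                d = 1 + max(depth(fi), depth(mi))
            memo[k] = d
            return d

        return [depth(k) for k in range(len(self.individuals))]


class KinshipMatrix:
    """Additive relationship matrix ``A = 2K`` over sampled individuals.

    Stored block-by-block (one block per family, families contiguous).
    ``ids`` are ``"fid:iid"`` composites aligned with the row order of any
    data matrix built from the same pedigree.
    """

    def __init__(self, ids: Sequence[str], family: Sequence[str], blocks: list[np.ndarray]):
        self.ids = list(ids)
        self.family = list(family)
        self.blocks = [np.asarray(b, dtype=float) for b in blocks]
        sizes = [b.shape[0] for b in self.blocks]
        if sum(sizes) != len(self.ids):
            raise ValueError("block sizes do not match number of ids")
        stops = np.cumsum(sizes)
        self.block_slices = [slice(int(stop - m), int(stop)) for m, stop in zip(sizes, stops)]
        self._eigens: list[tuple[np.ndarray, np.ndarray]] | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_families(self) -> int:
        return len(self.blocks)

    def full(self) -> np.ndarray:
        """Dense n x n matrix (zero between families)."""
        out = np.zeros((self.n, self.n))
        for sl, b in zip(self.block_slices, self.blocks):
            out[sl, sl] = b
        return out

    def eigens(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Cached per-family eigendecompositions ``(U_f, s_f)`` of each block."""
        if self._eigens is None:
            eig = []
            for b in self.blocks:
                s, U = np.linalg.eigh(b)
                eig.append((U, s))
            self._eigens = eig
        return self._eigens

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.full(), index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "KinshipMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(c) for c in df.columns]
        fams = [i.split(":", 1)[0] for i in ids]
        mat = df.to_numpy(dtype=float)
        blocks = []
        start = 0
        for k in range(1, len(ids) + 1):
            if k == len(ids) or fams[k] != fams[start]:
                blocks.append(mat[start:k, start:k])
                start = k
        return cls(ids, fams, blocks)


@dataclasses.dataclass
class GenotypeMatrix:
    """Allele counts in {0,1,2} for sampled individuals, one column per SNP."""

    matrix: np.ndarray  # n x q
    maf: np.ndarray  # length q sample minor-allele frequencies
    ids: list[str]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def q(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# kinship computation
# ---------------------------------------------------------------------------

def kinship_from_pedigree(ped: Pedigree) -> KinshipMatrix:
    """Compute ``A = 2K`` by the tabular recursion, restricted to sampled members.

    For individuals ordered parents-first:
    ``A_ii = 1 + A(father_i, mother_i) / 2`` and
    ``A_ij = (A(j, father_i) + A(j, mother_i)) / 2`` for earlier *j*,
    with founders unrelated and non-inbred.  Unsampled connectors
    participate in the recursion and are dropped from the output.
    """
    ids: list[str] = []
    fams: list[str] = []
    blocks: list[np.ndarray] = []
    order = ped.topological()
    by_family: dict[str, list[Individual]] = {}
    for k in order:
        ind = ped.individuals[k]
        by_family.setdefault(ind.fid, []).append(ind)
    for fid in ped.families:
        members = by_family[fid]
        pos = {ind.iid: j for j, ind in enumerate(members)}
        m = len(members)
        A = np.zeros((m, m))
        for j, ind in enumerate(members):
            if ind.father is None:
                A[j, j] = 1.0
                fa = mo = None
            else:
                fa, mo = pos[ind.father], pos[ind.mother]
                A[j, j] = 1.0 + 0.5 * A[fa, mo]
            for i in range(j):
                if fa is None:
                    a = 0.0
                else:
                    a = 0.5 * (A[i, fa] + A[i, mo])
                A[i, j] = A[j, i] = a
        keep = [j for j, ind in enumerate(members) if ind.sampled]
        blocks.append(A[np.ix_(keep, keep)])
        for j in keep:
            ids.append(f"{fid}:{members[j].iid}")
            fams.append(fid)
    return KinshipMatrix(ids, fams, blocks)


# ---------------------------------------------------------------------------
# synthetic cohorts
# ---------------------------------------------------------------------------

def _sibship_template(fid: str) -> list[Individual]:
    # Two full siblings (parents unsampled), each with an unrelated spouse
    # and two children: 8 sampled members per family.  Within-family 2k
    # values: 1 (self), 0.5 (sibs, parent-child), 0.25 (avuncular),
    # 0.125 (first cousins), 0 (marry-ins).
    F = fid
    return [
        Individual("gf", F, None, None, 1, sampled=False),
        Individual("gm", F, None, None, 2, sampled=False),
        Individual("s1", F, "gf", "gm", 1),
        Individual("s2", F, "gf", "gm", 2),
        Individual("w1", F, None, None, 2),
        Individual("w2", F, None, None, 1),
        Individual("c11", F, "s1", "w1", 1),
        Individual("c12", F, "s1", "w1", 2),
        Individual("c21", F, "w2", "s2", 1),
        Individual("c22", F, "w2", "s2", 2),
    ]


#: family templates by name; "5-node-cluster" is the clustering used by the
#: five-variable network study (581 independent family clusters).
FAMILY_TEMPLATES = {
    "sibship-8": _sibship_template,
    "5-node-cluster": _sibship_template,
}


def make_synthetic_cohort(n_families: int, template: str = "sibship-8", seed: int = 0) -> Pedigree:
    """Replicate a family template ``n_families`` times.

    The default template yields 8 sampled members per family, so 582
    families give a cohort of 4656 sampled subjects.  Deterministic given
    ``seed`` (the built-in templates are non-random; the seed is part of
    the interface for templates with random composition).
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    try:
        build = FAMILY_TEMPLATES[template]
    except KeyError:
        raise KeyError(
            f"unknown family template {template!r}; available: {sorted(FAMILY_TEMPLATES)}"
        ) from None
    inds: list[Individual] = []
    for f in range(1, n_families + 1):
        inds.extend(build(str(f)))
    return Pedigree(inds)


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def gene_drop_snps(
    ped: Pedigree,
    q: int,
    maf_min: float = 0.05,
    seed: int | np.random.Generator = 0,
    max_redraws: int = 1000,
) -> GenotypeMatrix:
    """Simulate ``q`` biallelic SNPs by Mendelian transmission down ``ped``.

    Founder alleles are Bernoulli(p) with per-SNP ``p ~ Uniform(maf_min, 0.5)``;
    each non-founder inherits one uniformly chosen allele from each parent.
    Columns whose sample minor-allele frequency (over sampled individuals)
    falls below ``maf_min`` are redrawn, mirroring a screen for common SNPs.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    if not 0 < maf_min < 0.5:
        raise ValueError("maf_min must be in (0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_all = len(ped)
    order = ped.topological()
    depths = ped._depths()
    # generation layers for vectorized transmission
    founders = np.array([k for k in order if ped.individuals[k].father is None])
    layers: dict[int, list[int]] = {}
    for k in order:
        if ped.individuals[k].father is not None:
            layers.setdefault(depths[k], []).append(k)
    father_idx = np.zeros(n_all, dtype=np.int64)
    mother_idx = np.zeros(n_all, dtype=np.int64)
    for k, ind in enumerate(ped.individuals):
        if ind.father is not None:
            father_idx[k] = ped._index[(ind.fid, ind.father)]
            mother_idx[k] = ped._index[(ind.fid, ind.mother)]
    sampled_idx = np.array([k for k, ind in enumerate(ped.individuals) if ind.sampled])

    def drop(nsnp: int) -> tuple[np.ndarray, np.ndarray]:
        p = rng.uniform(maf_min, 0.5, size=nsnp)
        H = np.zeros((n_all, nsnp, 2), dtype=np.int8)
        H[founders] = (rng.random((founders.size, nsnp, 2)) < p[None, :, None]).astype(np.int8)
        for d in sorted(layers):
            kids = np.array(layers[d])
            pick_f = rng.integers(0, 2, size=(kids.size, nsnp))
            pick_m = rng.integers(0, 2, size=(kids.size, nsnp))
            rows = np.arange(kids.size)[:, None]
            cols = np.arange(nsnp)[None, :]
            H[kids, :, 0] = H[father_idx[kids]][rows, cols, pick_f]
            H[kids, :, 1] = H[mother_idx[kids]][rows, cols, pick_m]
        G = H.sum(axis=2)[sampled_idx]
        freq = G.mean(axis=0) / 2.0
        return G, np.minimum(freq, 1.0 - freq)

    G, maf = drop(q)
    for _ in range(max_redraws):
        bad = np.flatnonzero(maf < maf_min)
        if bad.size == 0:
            break
        G2, maf2 = drop(bad.size)
        G[:, bad] = G2
        maf[bad] = maf2
    else:
        raise RuntimeError(f"could not reach sample MAF >= {maf_min} after {max_redraws} redraws")
    ids = [f"{ped.individuals[k].fid}:{ped.individuals[k].iid}" for k in sampled_idx]
    return GenotypeMatrix(matrix=G.astype(np.int8), maf=maf, ids=ids)


# ---------------------------------------------------------------------------
# PED-style I/O (whitespace-delimited: fid iid father mother sex [sampled])
# ---------------------------------------------------------------------------

def read_ped(path) -> Pedigree:
    """Read a PED-style file: missing parents coded "0", optional 6th column
    is a 0/1 sampled flag (default 1)."""
    inds: list[Individual] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 5:
                raise PedigreeError(f"{path}: line {ln}: expected >= 5 columns, got {len(fields)}")
            fid, iid, fa, mo, sex = fields[:5]
            sampled = True
            if len(fields) >= 6:
                sampled = fields[5] not in ("0", "-9")
            inds.append(
                Individual(
                    iid=iid,
                    fid=fid,
                    father=None if fa == "0" else fa,
                    mother=None if mo == "0" else mo,
                    sex=int(sex) if sex.isdigit() else 0,
                    sampled=sampled,
                )
            )
    if not inds:
        raise PedigreeError(f"{path}: no individuals")
    return Pedigree(inds)


def write_ped(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        for ind in ped.individuals:
            fh.write(
                f"{ind.fid}\t{ind.iid}\t{ind.father or 0}\t{ind.mother or 0}"
                f"\t{ind.sex}\t{int(ind.sampled)}\n"
            )
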