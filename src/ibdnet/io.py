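"""File formats for the association/network pipeline.

Four dialects are handled: a genotype table (plain TSV or a minimal
PED/MAP pair), a protein-interaction edge list in the STRING detailed-TSV
style, gene sets in GMT, and the packaged risk-SNP reference panel.
Every reader validates on load and either returns a consistent object or
raises :class:`LoadError` naming the offending line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # genotype code for a missing call

__all__ = [
    "LoadError",
    "SnpMeta",
    "GenotypeMatrix",
    "InteractionTable",
    "GeneSetDB",
    "read_genotypes",
    "write_genotypes",
    "read_interactions",
    "write_interactions",
    "read_gmt",
    "write_gmt",
    "read_table2_fixture",
    "TABLE2_RSID_NORMALIZATION",
]


class LoadError(ValueError):
    """A file failed validation on load."""


@dataclass(frozen=True)
class SnpMeta:
    """Annotation for one SNP: rsID, chromosome, locus symbol and alleles.

    ``a1`` is the minor allele (the one whose copies the genotype code
    counts); ``a2`` the major allele. Indels may use a ``-`` token.
    """

    snp_id: str
    chrom: str = "0"
    locus: str = ""
    a1: str = "A"
    a2: str = "G"

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be nonempty")
        if self.a1 == self.a2:
            raise ValueError(f"{self.snp_id}: a1 and a2 must differ")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs genotype calls coded as copies of allele 1.

    ``calls[i, j]`` is 0, 1, 2 or :data:`MISSING` for sample ``i`` at SNP
    ``j``. Group labels assign each sample to a phenotype (e.g. HC, CD,
    UC, B1..E3).
    """

    samples: list[str]
    groups: dict[str, str]
    snps: list[SnpMeta]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        missing_groups = [s for s in self.samples if s not in self.groups]
        if missing_groups:
            raise ValueError(f"samples without group label: {missing_groups[:5]}")
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(f"invalid genotype code at sample {bad[0]}, snp {bad[1]}")
        ids = [m.snp_id for m in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP IDs in panel")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self, snp_id: str) -> int:
        for i, m in enumerate(self.snps):
            if m.snp_id == snp_id:
                return i
        raise KeyError(snp_id)

    def group_mask(self, label: str) -> np.ndarray:
        return np.array([self.groups[s] == label for s in self.samples], dtype=bool)

    def group_labels(self) -> set[str]:
        return set(self.groups[s] for s in self.samples)

    def n_missing(self) -> int:
        return int((self.calls == MISSING).sum())


@dataclass
class InteractionTable:
    """Protein-protein association records with combined confidence scores.

    Stores each unordered pair once with the maximum combined score seen;
    self-pairs are dropped on construction. Optional per-channel scores
    (textmining, experiments, ...) travel along but never gate edges.
    """

    records: pd.DataFrame  # columns: protein_a, protein_b, combined_score, ...

    def __post_init__(self) -> None:
        df = self.records
        required = ("protein_a", "protein_b", "combined_score")
        for col in required:
            if col not in df.columns:
                raise ValueError(f"missing column {col}")
        s = df["combined_score"]
        if len(df) and ((s < 0) | (s > 1)).any():
            raise ValueError("combined_score outside [0, 1]")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def proteins(self) -> set[str]:
        return set(self.records["protein_a"]) | set(self.records["protein_b"])

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        for row in self.records.itertuples(index=False):
            yield row.protein_a, row.protein_b, float(row.combined_score)


@dataclass
class GeneSetDB:
    """Ordered gene-set database (set id -> description + member symbols)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, (_desc, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {sid} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {sid} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def members(self, set_id: str) -> list[str]:
        return self.sets[set_id][1]

    def description(self, set_id: str) -> str:
        return self.sets[set_id][0]

    def ids(self) -> list[str]:
        return list(self.sets)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _sid, (_d, members) in self.sets.items():
            out.update(members)
        return out


# ---------------------------------------------------------------------------
# genotype dialects
# ---------------------------------------------------------------------------

_GENO_TOKENS = {"0": 0, "1": 1, "2": 2, "NA": MISSING, "": MISSING, ".": MISSING}


def read_genotypes(
    path: str | Path,
    dialect: str = "tsv",
    snp_meta: Mapping[str, SnpMeta] | None = None,
) -> GenotypeMatrix:
    """Load a genotype matrix from a TSV table or a minimal PED/MAP pair.

    TSV dialect: header ``sample<TAB>group<TAB>rs1<TAB>rs2...``, cells
    0/1/2/NA counting copies of allele 1. PED/MAP dialect: ``path`` is the
    PED file and the MAP file sits next to it with suffix ``.map``; the MAP
    may carry a1/a2 in columns 5-6, otherwise allele 1 is taken to be the
    observed minor allele (lexicographic on ties). Unknown genotype tokens
    become missing with a logged warning count.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    if dialect == "tsv":
        return _read_genotypes_tsv(path, snp_meta)
    if dialect == "pedmap":
        return _read_genotypes_pedmap(path, snp_meta)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_genotypes_tsv(path: Path, snp_meta) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[0] != "sample" or header[1] != "group":
            raise LoadError(f"{path}:1: malformed header (want sample, group, rsIDs)")
        snp_ids = header[2:]
        if len(set(snp_ids)) != len(snp_ids):
            raise LoadError(f"{path}:1: duplicated SNP ID in header")
        samples: list[str] = []
        groups: dict[str, str] = {}
        rows: list[list[int]] = []
        n_unknown = 0
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise LoadError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            sid, grp = fields[0], fields[1]
            if sid in groups:
                raise LoadError(f"{path}:{lineno}: duplicated sample ID {sid!r}")
            row = []
            for tok in fields[2:]:
                if tok in _GENO_TOKENS:
                    row.append(_GENO_TOKENS[tok])
                else:
                    n_unknown += 1
                    row.append(MISSING)
            samples.append(sid)
            groups[sid] = grp
            rows.append(row)
    if n_unknown:
        logger.warning("%s: %d unknown genotype tokens treated as missing", path, n_unknown)
    metas = [
        (snp_meta or {}).get(s) or SnpMeta(snp_id=s, locus=s) for s in snp_ids
    ]
    calls = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(snp_ids)), np.int8)
    return GenotypeMatrix(samples=samples, groups=groups, snps=metas, calls=calls)


def _read_genotypes_pedmap(ped_path: Path, snp_meta) -> GenotypeMatrix:
    map_path = ped_path.with_suffix(".map")
    if not map_path.exists():
        raise LoadError(f"no MAP file next to {ped_path}")
    metas: list[SnpMeta | None] = []
    snp_ids: list[str] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if len(fields) < 4:
                raise LoadError(f"{map_path}:{lineno}: expected >=4 fields")
            chrom, sid = fields[0], fields[1]
            snp_ids.append(sid)
            if len(fields) >= 6:  # extended dialect with a1/a2
                metas.append(SnpMeta(snp_id=sid, chrom=chrom, locus=sid, a1=fields[4], a2=fields[5]))
            elif snp_meta and sid in snp_meta:
                metas.append(snp_meta[sid])
            else:
                metas.append(None)  # alleles inferred from data below

    samples: list[str] = []
    groups: dict[str, str] = {}
    allele_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if len(fields) != 6 + 2 * len(snp_ids):
                raise LoadError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * len(snp_ids)} fields, "
                    f"got {len(fields)}"
                )
            sid = fields[1]
            if sid in groups:
                raise LoadError(f"{ped_path}:{lineno}: duplicated sample ID {sid!r}")
            samples.append(sid)
            groups[sid] = fields[5]
            allele_rows.append(
                [(fields[6 + 2 * j], fields[7 + 2 * j]) for j in range(len(snp_ids))]
            )

    # infer a1 (minor) / a2 where the MAP did not provide them
    for j, meta in enumerate(metas):
        if meta is not None:
            continue
        counts: dict[str, int] = {}
        for row in allele_rows:
            for al in row[j]:
                if al != "0":
                    counts[al] = counts.get(al, 0) + 1
        alleles = sorted(counts, key=lambda a: (counts[a], a))
        if len(alleles) == 1:
            alleles.append("N" if alleles[0] != "N" else "X")
        elif not alleles:
            alleles = ["A", "G"]
        metas[j] = SnpMeta(snp_id=snp_ids[j], locus=snp_ids[j], a1=alleles[0], a2=alleles[-1])

    calls = np.full((len(samples), len(snp_ids)), MISSING, dtype=np.int8)
    n_unknown = 0
    for i, row in enumerate(allele_rows):
        for j, (x, y) in enumerate(row):
            meta = metas[j]
            if x == "0" or y == "0":
                continue
            dose = 0
            bad = False
            for al in (x, y):
                if al == meta.a1:
                    dose += 1
                elif al != meta.a2:
                    bad = True
            if bad:
                n_unknown += 1
                continue
            calls[i, j] = dose
    if n_unknown:
        logger.warning("%s: %d unrecognized alleles treated as missing", ped_path, n_unknown)
    return GenotypeMatrix(samples=samples, groups=groups, snps=list(metas), calls=calls)


def write_genotypes(matrix: GenotypeMatrix, path: str | Path, dialect: str = "tsv") -> None:
    """Write a genotype matrix; for ``pedmap`` the MAP gains a1/a2 columns."""
    path = Path(path)
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("sample\tgroup\t" + "\t".join(m.snp_id for m in matrix.snps) + "\n")
            for i, s in enumerate(matrix.samples):
                cells = [
                    "NA" if c == MISSING else str(int(c)) for c in matrix.calls[i]
                ]
                fh.write(f"{s}\t{matrix.groups[s]}\t" + "\t".join(cells) + "\n")
        return
    if dialect == "pedmap":
        map_path = path.with_suffix(".map")
        with open(map_path, "w") as fh:
            for m in matrix.snps:
                fh.write(f"{m.chrom}\t{m.snp_id}\t0\t0\t{m.a1}\t{m.a2}\n")
        with open(path, "w") as fh:
            for i, s in enumerate(matrix.samples):
                pairs = []
                for j, m in enumerate(matrix.snps):
                    c = matrix.calls[i, j]
                    if c == MISSING:
                        pairs.append("0 0")
                    else:
                        pairs.append(" ".join([m.a1] * int(c) + [m.a2] * (2 - int(c))))
                fh.write(f"FAM {s} 0 0 0 {matrix.groups[s]} " + " ".join(pairs) + "\n")
        return
    raise ValueError(f"unknown genotype dialect {dialect!r}")


# ---------------------------------------------------------------------------
# interaction edge lists
# ---------------------------------------------------------------------------

def read_interactions(path: str | Path, min_score: float = 0.0) -> InteractionTable:
    """Load a protein-interaction TSV and keep pairs with score >= min_score.

    Scores may be on the 0-1000 integer scale (divided by 1000) or already
    in [0, 1]; the dialect is auto-detected from the maximum value. Duplicate
    unordered pairs collapse to their maximum score; self-loops are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in df.columns}
    try:
        pa, pb, cs = cols["protein1"], cols["protein2"], cols["combined_score"]
    except KeyError as exc:
        raise LoadError(f"{path}: missing column {exc}") from None
    df = df.rename(columns={pa: "protein_a", pb: "protein_b", cs: "combined_score"})
    scores = df["combined_score"].astype(float)
    if len(scores) and scores.max() > 1.0:  # 0-1000 integer dialect
        scores = scores / 1000.0
    if len(scores) and ((scores < 0) | (scores > 1)).any():
        raise LoadError(f"{path}: combined_score outside [0, 1] after normalization")
    df["combined_score"] = scores
    return build_interaction_table(df, min_score=min_score)


def build_interaction_table(df: pd.DataFrame, min_score: float = 0.0) -> InteractionTable:
    """Canonicalize an edge frame: drop self-loops, dedupe pairs, threshold."""
    df = df.copy()
    df = df[df["protein_a"] != df["protein_b"]]
    lo = df[["protein_a", "protein_b"]].min(axis=1)
    hi = df[["protein_a", "protein_b"]].max(axis=1)
    df["protein_a"], df["protein_b"] = lo, hi
    df = (
        df.sort_values("combined_score", ascending=False)
        .drop_duplicates(["protein_a", "protein_b"], keep="first")
    )
    df = df[df["combined_score"] >= min_score]
    df = df.sort_values(["protein_a", "protein_b"]).reset_index(drop=True)
    return InteractionTable(records=df)


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    df = table.records.rename(
        columns={"protein_a": "protein1", "protein_b": "protein2"}
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetDB:
    """Load a GMT file: ``set_id<TAB>description<TAB>gene1<TAB>gene2...``."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise LoadError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            sid, desc = fields[0], fields[1]
            if sid in sets:
                raise LoadError(f"{path}:{lineno}: duplicated set id {sid!r}")
            members: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                if g and g not in seen:
                    members.append(g)
                    seen.add(g)
            if not members:
                raise LoadError(f"{path}:{lineno}: set {sid!r} has no members")
            sets[sid] = (desc, members)
    return GeneSetDB(sets=sets)


def write_gmt(db: GeneSetDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, (desc, members) in db.sets.items():
            fh.write("\t".join([sid, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# packaged risk-SNP reference panel
# ---------------------------------------------------------------------------

#: Printed rsIDs in the source table's CD block are truncated; they are
#: normalized by locus + control-frequency match to the other blocks.
TABLE2_RSID_NORMALIZATION = {
    "rs1730982": "rs17309827",
    "rs1076165": "rs10761659",
    "rs1723465": "rs17234657",
    "rs1252919": "rs12529198",
}

PHENOTYPES = ("IBD", "CD", "UC", "B1", "B2", "B3", "E1", "E2", "E3")


@dataclass(frozen=True)
class RiskSnpRecord:
    """One row of the packaged per-phenotype risk-SNP panel."""

    phenotype: str
    snp: SnpMeta
    f_A: float
    f_U: float
    chi2: float
    p: float
    or_: float


def _load_table2() -> pd.DataFrame:
    with resources.files("ibdnet.data").joinpath("table2.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str}).rename(columns={"or": "or_"})


def read_table2_fixture(phenotype: str | None = None) -> list[RiskSnpRecord]:
    """Return the packaged risk-SNP association panel, optionally one block.

    rsIDs are returned in normalized (full dbSNP) form; the printed form is
    recoverable through :data:`TABLE2_RSID_NORMALIZATION`. Frequencies are
    fractions (the source prints percent).
    """
    df = _load_table2()
    if phenotype is not None:
        if phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {phenotype!r}")
        df = df[df["phenotype"] == phenotype]
    out = []
    for row in df.itertuples(index=False):
        meta = SnpMeta(
            snp_id=row.snp, chrom=str(row.chrom), locus=row.locus, a1=row.a1, a2=row.a2
        )
        out.append(
            RiskSnpRecord(
                phenotype=row.phenotype,
                snp=meta,
                f_A=row.f_A_pct / 100.0,
                f_U=row.f_U_pct / 100.0,
                chi2=row.chi2,
                p=row.p,
                or_=row.or_,
            )
        )
    return out
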