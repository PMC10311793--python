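"""Genotype containers, SNP-to-gene grouping, and text/PLINK-raw I/O.

Genotypes are additive minor-allele dosages in {0, 1, 2}, stored SNPs x
subjects.  SNPs are partitioned into genes; multiple SNPs on one gene often
jointly carry a genetic signal, which is what the group-sparse prior
downstream exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "GroupPartition", "read_plink_raw", "write_plink_raw",
           "read_partition", "write_partition"]


@dataclass
class GroupPartition:
    """Disjoint, exhaustive partition of SNP indices into Q gene groups."""

    groups: list[np.ndarray]
    names: list[str]

    def __post_init__(self) -> None:
        self.groups = [np.asarray(g, dtype=int) for g in self.groups]
        if len(self.names) != len(self.groups):
            raise ValueError("one name per group required")
        all_idx = np.concatenate(self.groups) if self.groups else np.array([], dtype=int)
        n = len(all_idx)
        if n and (len(np.unique(all_idx)) != n or all_idx.min() != 0 or all_idx.max() != n - 1):
            raise ValueError("groups must disjointly and exhaustively cover 0..S-1")
        if any(len(g) == 0 for g in self.groups):
            raise ValueError("empty group")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_items(self) -> int:
        return sum(len(g) for g in self.groups)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(g) for g in self.groups])

    def labels(self) -> np.ndarray:
        """Per-SNP integer group label, length S."""
        lab = np.empty(self.n_items, dtype=int)
        for q, g in enumerate(self.groups):
            lab[g] = q
        return lab

    def gene_of(self) -> list[str]:
        """Per-SNP gene name, length S."""
        names = [""] * self.n_items
        for q, g in enumerate(self.groups):
            for i in g:
                names[i] = self.names[q]
        return names

    @classmethod
    def from_labels(cls, labels) -> "GroupPartition":
        """Build from a per-SNP sequence of gene labels (first-seen order)."""
        labels = [str(x) for x in labels]
        order: list[str] = []
        seen: dict[str, list[int]] = {}
        for i, lab in enumerate(labels):
            if lab not in seen:
                seen[lab] = []
                order.append(lab)
            seen[lab].append(i)
        return cls([np.array(seen[g]) for g in order], order)

    def subset(self, indices) -> "GroupPartition":
        """Partition induced on a subset of SNP positions (e.g. after screening).

        ``indices`` are positions in the original 0..S-1 indexing; groups that
        become empty are dropped, and indices are renumbered 0..len-1 in the
        order given.
        """
        indices = np.asarray(indices, dtype=int)
        pos = {int(old): new for new, old in enumerate(indices)}
        groups, names = [], []
        for name, g in zip(self.names, self.groups):
            kept = [pos[int(i)] for i in g if int(i) in pos]
            if kept:
                groups.append(np.array(sorted(kept)))
                names.append(name)
        return GroupPartition(groups, names)


@dataclass
class GenotypeMatrix:
    """SNPs x subjects additive dosage matrix with SNP and subject identifiers."""

    values: np.ndarray
    snp_ids: list[str]
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.subject_ids = [str(s) for s in self.subject_ids]
        if self.values.shape != (len(self.snp_ids), len(self.subject_ids)):
            raise ValueError("genotype shape does not match identifier lengths")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp_ids must be unique")

    @property
    def n_snps(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]

    def dosages(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def subset_snps(self, row_indices) -> "GenotypeMatrix":
        row_indices = np.asarray(row_indices, dtype=int)
        return GenotypeMatrix(
            self.values[row_indices], [self.snp_ids[i] for i in row_indices],
            list(self.subject_ids),
        )

    def subset_subjects(self, mask) -> "GenotypeMatrix":
        idx = np.flatnonzero(np.asarray(mask))
        return GenotypeMatrix(
            self.values[:, idx], list(self.snp_ids),
            [self.subject_ids[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.T, index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.snp_ids,
        )


def write_plink_raw(genotype: GenotypeMatrix, path, sex=None, phenotype=None) -> None:
    """Write the PLINK additive-recode (``--recode A``) text dialect.

    Header ``FID IID PAT MAT SEX PHENOTYPE`` followed by one ``<snp>_A``
    column per SNP; one row per subject, space-separated.
    """
    n = genotype.n_subjects
    sex = np.asarray(sex if sex is not None else np.zeros(n, dtype=int))
    phenotype = np.asarray(phenotype if phenotype is not None else -9 * np.ones(n, dtype=int))
    cols = [f"{s}_A" for s in genotype.snp_ids]
    with open(path, "w") as fh:
        fh.write(" ".join(["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"] + cols) + "\n")
        for j, sid in enumerate(genotype.subject_ids):
            row = [sid, sid, "0", "0", str(int(sex[j])), str(int(phenotype[j]))]
            row += [str(int(v)) for v in genotype.values[:, j]]
            fh.write(" ".join(row) + "\n")


def read_plink_raw(path) -> GenotypeMatrix:
    """Read a PLINK additive-recode (.raw) file into a :class:`GenotypeMatrix`."""
    df = pd.read_csv(path, sep=r"\s+")
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ValueError(f".raw header missing columns {missing}")
    snp_cols = [c for c in df.columns if c not in meta]
    snp_ids = [c[:-2] if c.endswith("_A") else c for c in snp_cols]
    values = df[snp_cols].to_numpy(dtype=float).T
    return GenotypeMatrix(values, snp_ids, [str(s) for s in df["IID"]])


def write_partition(partition: GroupPartition, snp_ids: list[str], path) -> None:
    """Write the SNP-to-gene map as two-column (snp_id, gene_id) text."""
    pd.DataFrame({"snp_id": snp_ids, "gene_id": partition.gene_of()}).to_csv(
        path, sep="\t", index=False
    )


def read_partition(path, snp_ids: list[str]) -> GroupPartition:
    """Read a two-column SNP-to-gene map, aligned to ``snp_ids`` order."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    missing = [s for s in snp_ids if s not in mapping]
    if missing:
        raise ValueError(f"partition file lacks gene for SNPs {missing[:5]}")
    return GroupPartition.from_labels([mapping[s] for s in snp_ids])
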