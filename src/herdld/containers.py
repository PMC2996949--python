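"""Shared data containers for the LD analysis pipeline.

Conventions used throughout the package:

* genotypes are coded 0/1/2 as the count of the lexicographically smaller
  allele; ``-1`` marks a missing call;
* haplotype alleles are coded 0/1 with ``-1`` for unknown phase (or an
  absent gamete, e.g. the paternal X-specific segment of a male);
* physical coordinates are 1-based inclusive base pairs, as in MAP files;
* chromosome labels are strings ``"1"``..``"29"`` and ``"X"`` (the bovine
  chip convention ``"30"`` is normalized to ``"X"`` on input).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

REGION_AUTOSOMAL = "autosomal"
REGION_X_SPECIFIC = "x_specific"
REGION_PAR = "par"
REGION_UNKNOWN = "unknown"

X_CHROM = "X"

ORIGIN_MATERNAL = "M"
ORIGIN_PATERNAL = "P"

SEX_MALE = "M"
SEX_FEMALE = "F"


def normalize_chrom(label) -> str:
    """Map a chromosome label to the internal convention ('30' -> 'X')."""
    s = str(label).strip()
    if s.upper() in ("X", "30"):
        return X_CHROM
    return s


def _as_str_object(values) -> np.ndarray:
    """Object-dtype string array (fixed-width unicode would truncate on
    later element assignment)."""
    return np.array([str(v) for v in values], dtype=object)


def _chrom_sort_key(label: str):
    return (1, 0) if label == X_CHROM else (0, int(label))


class SnpMap:
    """Ordered marker catalog: id, chromosome, bp position, region tag.

    Markers are stored sorted by (chromosome, position); positions must be
    strictly increasing within each chromosome and ids unique.
    """

    def __init__(self, ids: Sequence[str], chrom: Sequence, pos: Sequence[int],
                 region: Sequence[str] | None = None):
        ids = _as_str_object(ids)
        chrom = np.array([normalize_chrom(c) for c in chrom], dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        if region is None:
            region = np.where(chrom == X_CHROM, REGION_UNKNOWN, REGION_AUTOSOMAL)
        region = _as_str_object(region)
        if not (len(ids) == len(chrom) == len(pos) == len(region)):
            raise ValueError("SnpMap columns must have equal length")
        order = sorted(range(len(ids)), key=lambda k: (_chrom_sort_key(chrom[k]), pos[k]))
        order = np.asarray(order, dtype=np.intp)
        self.ids = ids[order]
        self.chrom = chrom[order]
        self.pos = pos[order]
        self.region = region[order]
        self._input_order = order  # original index of each (sorted) marker
        self._validate()

    def _validate(self):
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("marker ids must be unique")
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
        bad = np.isin(self.region, (REGION_PAR, REGION_X_SPECIFIC)) & (self.chrom != X_CHROM)
        if bad.any():
            raise ValueError("region par/x_specific allowed only on chromosome X")

    def __len__(self):
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.ids)

    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for c in self.chrom:
            if c not in seen:
                seen.append(c)
        return seen

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == normalize_chrom(chrom))

    def index_of(self, marker_id: str) -> int:
        hit = np.flatnonzero(self.ids == marker_id)
        if len(hit) != 1:
            raise KeyError(marker_id)
        return int(hit[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "chrom": self.chrom,
                             "pos": self.pos, "region": self.region})

    def with_positions(self, new_pos: np.ndarray) -> "SnpMap":
        """Return a new map with updated positions (re-sorted)."""
        return SnpMap(self.ids, self.chrom, new_pos, self.region)

    def with_regions(self, region: Sequence[str]) -> "SnpMap":
        return SnpMap(self.ids, self.chrom, self.pos, region)

    def __eq__(self, other):
        return (isinstance(other, SnpMap)
                and np.array_equal(self.ids, other.ids)
                and np.array_equal(self.chrom, other.chrom)
                and np.array_equal(self.pos, other.pos)
                and np.array_equal(self.region, other.region))


class Pedigree:
    """Animal pedigree: id, sire id, dam id ('0' = unknown), sex ('M'/'F')."""

    def __init__(self, ids: Sequence[str], sire: Sequence[str], dam: Sequence[str],
                 sex: Sequence[str]):
        self.frame = pd.DataFrame({
            "id": _as_str_object(ids),
            "sire": _as_str_object(sire),
            "dam": _as_str_object(dam),
            "sex": _as_str_object(sex),
        })
        if self.frame["id"].duplicated().any():
            raise ValueError("duplicate animal ids in pedigree")
        self._check_acyclic()

    def _check_acyclic(self):
        parent = {}
        for _, row in self.frame.iterrows():
            parent[row["id"]] = [p for p in (row["sire"], row["dam"]) if p != "0"]
        for start in parent:
            stack, seen = list(parent[start]), set()
            while stack:
                a = stack.pop()
                if a == start:
                    raise ValueError(f"animal {start} is its own ancestor")
                if a in seen:
                    continue
                seen.add(a)
                stack.extend(parent.get(a, []))

    def __len__(self):
        return len(self.frame)

    @property
    def ids(self) -> np.ndarray:
        return self.frame["id"].to_numpy()

    def sire_of(self, animal: str) -> str:
        row = self.frame.loc[self.frame["id"] == animal]
        return row["sire"].iloc[0] if len(row) else "0"

    def sex_of(self, animal: str) -> str:
        row = self.frame.loc[self.frame["id"] == animal]
        return row["sex"].iloc[0] if len(row) else "0"


@dataclass
class ArtifactLedger:
    """Ground-truth record of artifacts injected into a simulated study."""

    misplaced: list = field(default_factory=list)      # (marker_id, true_pos, displayed_pos)
    mendel_errors: list = field(default_factory=list)  # (animal_id, marker_id)
    missing: list = field(default_factory=list)        # (animal_id, marker_id)

    def is_empty(self) -> bool:
        return not (self.misplaced or self.mendel_errors or self.missing)


class HaplotypePanel:
    """Phase-resolved binary allele matrix with per-haplotype labels.

    ``alleles`` is (n_haplotypes x n_markers) int8 with entries 0/1 and -1
    for unknown phase; ``carrier`` and ``origin`` give, per row, the animal
    carrying the haplotype and its parental origin ('M' maternal /
    'P' paternal / 'U' unlabeled).
    """

    def __init__(self, alleles: np.ndarray, carrier: Sequence[str],
                 origin: Sequence[str] | None = None):
        self.alleles = np.asarray(alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D haplotypes x markers matrix")
        self.carrier = _as_str_object(carrier)
        if origin is None:
            origin = np.full(len(self.carrier), "U", dtype=object)
        self.origin = _as_str_object(origin)
        if not (self.alleles.shape[0] == len(self.carrier) == len(self.origin)):
            raise ValueError("carrier/origin labels must match haplotype rows")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def subset_rows(self, rows: np.ndarray) -> "HaplotypePanel":
        return HaplotypePanel(self.alleles[rows], self.carrier[rows], self.origin[rows])

    def subset_markers(self, cols: np.ndarray) -> "HaplotypePanel":
        return HaplotypePanel(self.alleles[:, cols], self.carrier, self.origin)

    def marker_freqs(self) -> np.ndarray:
        """Frequency of allele 1 per marker among known alleles (NaN if none)."""
        known = self.alleles >= 0
        num = np.where(known, self.alleles, 0).sum(axis=0).astype(float)
        den = known.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / den, np.nan)

    def marker_maf(self) -> np.ndarray:
        f = self.marker_freqs()
        return np.minimum(f, 1.0 - f)


@dataclass
class StudyTruth:
    """Simulator-provided ground truth attached to a synthetic study."""

    panel: HaplotypePanel
    ledger: ArtifactLedger = field(default_factory=ArtifactLedger)
    par_start: int | None = None  # true first PAR bp on X, if an X was simulated


class Study:
    """Genotype matrix + marker map + pedigree (+ optional simulator truth).

    ``genotypes`` is (n_animals x n_markers) int8 in {0,1,2,-1}; rows follow
    ``animal_ids``; columns follow the sorted ``snp_map``. ``study_ids``
    names the analysis cohort (e.g. the half-sib progeny); parents may be
    present as extra genotyped rows for pedigree checks.
    """

    def __init__(self, genotypes: np.ndarray, animal_ids: Sequence[str],
                 snp_map: SnpMap, pedigree: Pedigree | None = None,
                 study_ids: Sequence[str] | None = None,
                 truth: StudyTruth | None = None):
        self.genotypes = np.asarray(genotypes, dtype=np.int8)
        self.animal_ids = _as_str_object(animal_ids)
        if self.genotypes.shape != (len(self.animal_ids), len(snp_map)):
            raise ValueError("genotype matrix shape does not match animals x markers")
        self.snp_map = snp_map
        self.pedigree = pedigree
        self.study_ids = (_as_str_object(study_ids)
                          if study_ids is not None else self.animal_ids.copy())
        self.truth = truth
        self._index = {a: i for i, a in enumerate(self.animal_ids)}

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return len(self.snp_map)

    def animal_index(self, animal: str) -> int:
        return self._index[animal]

    def has_animal(self, animal: str) -> bool:
        return animal in self._index

    def genotypes_of(self, animals: Iterable[str]) -> np.ndarray:
        rows = [self._index[a] for a in animals]
        return self.genotypes[rows]

    def males(self) -> list[str]:
        if self.pedigree is None:
            return []
        sex = dict(zip(self.pedigree.frame["id"], self.pedigree.frame["sex"]))
        return [a for a in self.study_ids if sex.get(a) == SEX_MALE]

    def marker_maf(self) -> np.ndarray:
        """Per-marker minor allele frequency from non-missing genotypes."""
        g = self.genotypes
        known = g >= 0
        num = np.where(known, g, 0).sum(axis=0).astype(float)
        den = 2.0 * known.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(den > 0, num / den, np.nan)
        return np.minimum(f, 1.0 - f)

    def call_rate(self) -> np.ndarray:
        return (self.genotypes >= 0).mean(axis=0)

    def copy(self) -> "Study":
        return Study(self.genotypes.copy(), self.animal_ids.copy(), self.snp_map,
                     self.pedigree, self.study_ids.copy(), self.truth)

    def subset_markers(self, cols: np.ndarray) -> "Study":
        sub_map = SnpMap(self.snp_map.ids[cols], self.snp_map.chrom[cols],
                         self.snp_map.pos[cols], self.snp_map.region[cols])
        truth = self.truth
        if truth is not None:
            truth = StudyTruth(truth.panel.subset_markers(cols), truth.ledger,
                               truth.par_start)
        return Study(self.genotypes[:, cols], self.animal_ids, sub_map,
                     self.pedigree, self.study_ids, truth)
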