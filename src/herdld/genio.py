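"""Readers and writers for the text formats the pipeline touches.

PED/MAP is the PLINK text dialect: MAP columns are chromosome, marker id,
genetic distance (ignored), bp position; PED rows are family, animal, sire,
dam, sex, phenotype, then two allele columns per marker. Genotypes are
coded 0/1/2 by counting the lexicographically smaller observed allele;
"0 0" is a missing call. Internal coordinates are 1-based inclusive bp;
BED input (0-based half-open) is converted on read. Chromosome "30" is
accepted as a synonym for "X".
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (MISSING, Pedigree, SEX_FEMALE, SEX_MALE, SnpMap,
                         Study, HaplotypePanel)

_SEX_CODES = {"1": SEX_MALE, "2": SEX_FEMALE, "M": SEX_MALE, "F": SEX_FEMALE}


def read_map(map_path) -> SnpMap:
    rows = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            rows.append((parts[1], parts[0], int(parts[3])))
    ids = [r[0] for r in rows]
    chrom = [r[1] for r in rows]
    pos = [r[2] for r in rows]
    return SnpMap(ids, chrom, pos)


def read_pedigree(path) -> Pedigree:
    ids, sire, dam, sex = [], [], [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(parts[0])
            sire.append(parts[1])
            dam.append(parts[2])
            sex.append(_SEX_CODES.get(parts[3].upper(), "0"))
    return Pedigree(ids, sire, dam, sex)


def read_study(ped_path, map_path, pedigree_path=None) -> Study:
    """Read a PED/MAP pair (and optional pedigree file) into a Study."""
    snp_map = read_map(map_path)
    m = len(snp_map)
    animal_ids, genos, ped_rows = [], [], []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"PED row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{(len(parts) - 6) // 2} allele pairs; map has {m} markers")
            animal_ids.append(parts[1])
            ped_rows.append((parts[1], parts[2], parts[3],
                             _SEX_CODES.get(parts[4], "0")))
            genos.append(parts[6:])
    n = len(animal_ids)
    geno = np.full((n, m), MISSING, dtype=np.int8)
    alleles_by_marker: list[dict] = [dict() for _ in range(m)]
    raw = np.array(genos, dtype=object).reshape(n, m, 2) if n else np.empty((0, m, 2))
    for k in range(m):
        obs = set(raw[:, k, :].ravel().tolist()) - {"0"} if n else set()
        if len(obs) > 2:
            raise ValueError(f"marker index {k} has more than 2 alleles: {sorted(obs)}")
        ordered = sorted(obs)
        alleles_by_marker[k] = {a: i for i, a in enumerate(ordered)}
    for k in range(m):
        small = min(alleles_by_marker[k]) if alleles_by_marker[k] else None
        for r in range(n):
            a1, a2 = raw[r, k, 0], raw[r, k, 1]
            if a1 == "0" or a2 == "0":
                continue
            geno[r, k] = int(a1 == small) + int(a2 == small)
    # PED columns follow the MAP file order; re-align to the sorted map
    geno = geno[:, snp_map._input_order]
    if pedigree_path is not None:
        pedigree = read_pedigree(pedigree_path)
    else:
        pedigree = Pedigree([r[0] for r in ped_rows], [r[1] for r in ped_rows],
                            [r[2] for r in ped_rows], [r[3] for r in ped_rows])
    return Study(geno, animal_ids, snp_map, pedigree)


def write_study(study: Study, prefix) -> tuple[Path, Path]:
    """Write a study as <prefix>.ped / <prefix>.map (sorted map order).

    Genotypes are rendered with alleles 'A' (the counted, lexicographically
    smaller allele) and 'B'; missing calls as '0 0'.
    """
    prefix = Path(prefix)
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    sm = study.snp_map
    with open(map_path, "w") as fh:
        for k in range(len(sm)):
            fh.write(f"{sm.chrom[k]}\t{sm.ids[k]}\t0\t{sm.pos[k]}\n")
    sire = {}
    dam = {}
    sex = {}
    if study.pedigree is not None:
        f = study.pedigree.frame
        sire = dict(zip(f["id"], f["sire"]))
        dam = dict(zip(f["id"], f["dam"]))
        sex = dict(zip(f["id"], f["sex"]))
    code = {0: "B B", 1: "A B", 2: "A A", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for r, aid in enumerate(study.animal_ids):
            sx = {"M": "1", "F": "2"}.get(sex.get(aid, "0"), "0")
            lead = [str(r + 1), aid, sire.get(aid, "0"), dam.get(aid, "0"), sx, "-9"]
            cells = [code[int(g)] for g in study.genotypes[r]]
            fh.write(" ".join(lead + cells) + "\n")
    return ped_path, map_path


def write_ld_table(table: pd.DataFrame, path) -> Path:
    """Tab-separated LD table; distance empty for non-syntenic pairs.

    Numbers round-trip at 10 significant digits.
    """
    path = Path(path)
    cols = ["id1", "id2", "chrom1", "chrom2", "distance_bp",
            "D", "abs_dprime", "r2", "mean_maf"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for row in table.itertuples(index=False):
            d = getattr(row, "distance_bp")
            w.writerow([row.id1, row.id2, row.chrom1, row.chrom2,
                        "" if pd.isna(d) else f"{int(d)}",
                        f"{row.D:.10g}", f"{row.abs_dprime:.10g}",
                        f"{row.r2:.10g}", f"{row.mean_maf:.10g}"])
    return path


def read_ld_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str,
                                            "id1": str, "id2": str})
    return df


def read_gene_bed(path) -> pd.DataFrame:
    """BED (0-based half-open) gene intervals -> 1-based closed DataFrame.

    Overlapping genes are retained as-is. Rejects lines with end <= start.
    """
    from .containers import normalize_chrom
    chroms, starts, ends, names = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith(("#", "track", "browser")):
                continue
            if len(parts) < 3:
                raise ValueError(f"BED line {lineno}: fewer than 3 columns")
            start0, end0 = int(parts[1]), int(parts[2])
            if end0 <= start0:
                raise ValueError(f"BED line {lineno}: end <= start")
            chroms.append(normalize_chrom(parts[0]))
            starts.append(start0 + 1)
            ends.append(end0)
            names.append(parts[3] if len(parts) > 3 else f"gene{lineno}")
    return pd.DataFrame({"chrom": chroms, "start": starts, "end": ends,
                         "name": names})


def write_haplotypes(panel: HaplotypePanel, snp_map: SnpMap, path) -> Path:
    """Truth/phase sidecar: one row per haplotype per chromosome.

    Columns: carrier animal, parent-of-origin (M/P/U), chromosome, allele
    string ('0'/'1', '?' for unknown phase).
    """
    path = Path(path)
    sym = {0: "0", 1: "1", MISSING: "?"}
    with open(path, "w") as fh:
        for h in range(panel.n_haplotypes):
            for chrom in snp_map.chromosomes():
                idx = snp_map.chrom_indices(chrom)
                s = "".join(sym[int(a)] for a in panel.alleles[h, idx])
                fh.write(f"{panel.carrier[h]}\t{panel.origin[h]}\t{chrom}\t{s}\n")
    return path


def read_haplotypes(path, snp_map: SnpMap) -> HaplotypePanel:
    rows: dict[tuple[str, str, int], dict[str, str]] = {}
    order: list[tuple[str, str, int]] = []
    with open(path) as fh:
        for line in fh:
            carrier, origin, chrom, s = line.split()
            # consecutive rows with the same carrier+origin belong together;
            # a repeat of an already-complete key starts a new haplotype
            key = (carrier, origin, 0)
            while key in rows and chrom in rows[key]:
                key = (carrier, origin, key[2] + 1)
            if key not in rows:
                rows[key] = {}
                order.append(key)
            rows[key][chrom] = s
    n = len(order)
    inv = {"0": 0, "1": 1, "?": MISSING}
    alleles = np.full((n, len(snp_map)), MISSING, dtype=np.int8)
    for h, key in enumerate(order):
        for chrom, s in rows[key].items():
            idx = snp_map.chrom_indices(chrom)
            if len(s) != len(idx):
                raise ValueError(f"haplotype string length mismatch on {chrom}")
            alleles[h, idx] = [inv[ch] for ch in s]
    carrier = [k[0] for k in order]
    origin = [k[1] for k in order]
    return HaplotypePanel(alleles, carrier, origin)


def write_ledger(ledger, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("kind\tanimal_or_marker\tmarker_or_true_pos\tdisplayed_pos\n")
        for mk, tp, dp in ledger.misplaced:
            fh.write(f"misplaced\t{mk}\t{tp}\t{dp}\n")
        for a, mk in ledger.mendel_errors:
            fh.write(f"mendel\t{a}\t{mk}\t\n")
        for a, mk in ledger.missing:
            fh.write(f"missing\t{a}\t{mk}\t\n")
    return path
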