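"""PLINK 1 text (PED/MAP) and binary (BED/BIM/FAM) readers and writers.

Implements the published PLINK 1 formats directly: MAP/BIM are whitespace
tables, PED carries two allele columns per marker, and BED is the SNP-major
2-bit encoding (magic ``0x6c 0x1b``, mode ``0x01``; per-genotype codes
00 = hom A1, 01 = missing, 10 = het, 11 = hom A2).  Dosage counts the A2 /
second-by-file allele, so text and binary readers agree bit-exactly.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .model import MISSING, GenotypeDataset, Marker, parse_chromosome

_BED_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = b"\x01"

# BED 2-bit code -> dosage of A2 (counted) allele
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
# dosage -> BED 2-bit code (index MISSING==-1 wraps to the last entry)
_BED_ENCODE = np.array([0b00, 0b10, 0b11, 0b01], dtype=np.uint8)


class PlinkFormatError(ValueError):
    """Malformed PLINK file (truncated row, bad magic, count mismatch...)."""


# ---------------------------------------------------------------------------
# text format
# ---------------------------------------------------------------------------

def _read_map(map_path: str | os.PathLike) -> list[tuple[int, str, int]]:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise PlinkFormatError(
                    f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}"
                )
            chrom, snp_id, _cm, bp = parts  # cM column read but unused
            rows.append((parse_chromosome(chrom), snp_id, int(bp)))
    return rows


def read_plink_text(
    ped_path: str | os.PathLike, map_path: str | os.PathLike
) -> GenotypeDataset:
    """Read a PED/MAP pair into a :class:`GenotypeDataset`.

    Dosage counts the second allele observed in file order at each marker
    ("allele B"); ``0 0`` pairs become missing.  Markers are re-sorted by
    (chromosome, bp) with genotype columns permuted consistently.
    """
    map_rows = _read_map(map_path)
    n_markers = len(map_rows)
    individuals: list[str] = []
    geno_rows: list[np.ndarray] = []
    # first/second allele seen per marker, in file order
    allele_a: list[str | None] = [None] * n_markers
    allele_b: list[str | None] = [None] * n_markers
    raw_pairs: list[list[tuple[str, str]]] = []

    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_markers:
                raise PlinkFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} fields "
                    f"for {n_markers} markers, got {len(parts)}"
                )
            individuals.append(parts[1])
            raw_pairs.append(
                [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_markers)]
            )

    # establish allele coding from file order of appearance
    for pairs in raw_pairs:
        for j, (a1, a2) in enumerate(pairs):
            for a in (a1, a2):
                if a == "0":
                    continue
                if allele_a[j] is None:
                    allele_a[j] = a
                elif allele_a[j] != a and allele_b[j] is None:
                    allele_b[j] = a
                elif a not in (allele_a[j], allele_b[j]):
                    raise PlinkFormatError(
                        f"{ped_path}: marker {map_rows[j][1]} has >2 alleles"
                    )

    for pairs in raw_pairs:
        row = np.empty(n_markers, dtype=np.int8)
        for j, (a1, a2) in enumerate(pairs):
            if a1 == "0" or a2 == "0":
                row[j] = MISSING
            else:
                row[j] = (a1 == allele_b[j]) + (a2 == allele_b[j])
        geno_rows.append(row)

    markers = [
        Marker(snp_id, chrom, bp, allele_a[j] or "A", allele_b[j] or "B")
        for j, (chrom, snp_id, bp) in enumerate(map_rows)
    ]
    geno = (
        np.vstack(geno_rows)
        if geno_rows
        else np.empty((0, n_markers), dtype=np.int8)
    )
    return GenotypeDataset(markers, individuals, geno)


# ---------------------------------------------------------------------------
# binary format
# ---------------------------------------------------------------------------

def _read_bim(bim_path: str | os.PathLike) -> list[Marker]:
    markers = []
    with open(bim_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise PlinkFormatError(
                    f"{bim_path}:{lineno}: expected 6 columns, got {len(parts)}"
                )
            chrom, snp_id, _cm, bp, a1, a2 = parts
            # BIM A1 is the counted allele in PLINK; we store it as allele_b
            markers.append(Marker(snp_id, parse_chromosome(chrom), int(bp), a2, a1))
    return markers


def _read_fam(fam_path: str | os.PathLike) -> list[str]:
    ids = []
    with open(fam_path) as fh:
        for line in fh:
            if line.strip():
                ids.append(line.split()[1])
    return ids


def read_plink_binary(
    bed_path: str | os.PathLike,
    bim_path: str | os.PathLike,
    fam_path: str | os.PathLike,
) -> GenotypeDataset:
    """Read a BED/BIM/FAM trio (SNP-major BED v1.00) into a dataset.

    Dosage counts the BIM A1 allele, matching PLINK's ``--recode A`` coding.
    """
    markers = _read_bim(bim_path)
    individuals = _read_fam(fam_path)
    n, m = len(individuals), len(markers)
    data = Path(bed_path).read_bytes()
    if len(data) < 3 or data[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad BED magic bytes")
    if data[2:3] != _SNP_MAJOR:
        raise PlinkFormatError(f"{bed_path}: only SNP-major BED supported")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(data) != expected:
        raise PlinkFormatError(
            f"{bed_path}: {len(data)} bytes, expected {expected} for "
            f"{n} individuals x {m} markers"
        )
    if m == 0 or n == 0:
        return GenotypeDataset(
            markers, individuals, np.empty((n, m), dtype=np.int8)
        )
    raw = np.frombuffer(data, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (raw >> (2 * k)) & 0b11
    geno = _BED_DECODE[codes[:, :n]].T  # -> (n, m)
    return GenotypeDataset(markers, individuals, np.ascontiguousarray(geno))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_plink(
    dataset: GenotypeDataset, prefix: str | os.PathLike, mode: str = "text"
) -> list[Path]:
    """Write ``dataset`` as PED/MAP (``mode="text"``) or BED/BIM/FAM.

    Round-trips bit-exactly through the matching reader.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if mode == "text":
        return _write_text(dataset, prefix)
    if mode == "binary":
        return _write_binary(dataset, prefix)
    raise ValueError(f"mode must be 'text' or 'binary', got {mode!r}")


def _write_text(dataset: GenotypeDataset, prefix: Path) -> list[Path]:
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    with open(map_path, "w") as fh:
        for mk in dataset.markers:
            fh.write(f"{mk.chromosome}\t{mk.id}\t0\t{mk.position_bp}\n")
    code = {
        0: lambda mk: (mk.allele_a, mk.allele_a),
        1: lambda mk: (mk.allele_a, mk.allele_b),
        2: lambda mk: (mk.allele_b, mk.allele_b),
        MISSING: lambda mk: ("0", "0"),
    }
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(dataset.individuals):
            fields = [iid, iid, "0", "0", "0", "-9"]
            for j, mk in enumerate(dataset.markers):
                fields.extend(code[int(dataset.genotypes[i, j])](mk))
            fh.write(" ".join(fields) + "\n")
    return [ped_path, map_path]


def _write_binary(dataset: GenotypeDataset, prefix: Path) -> list[Path]:
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    bed_path = prefix.with_suffix(".bed")
    with open(bim_path, "w") as fh:
        for mk in dataset.markers:
            # counted allele (allele_b) is written as BIM A1
            fh.write(
                f"{mk.chromosome}\t{mk.id}\t0\t{mk.position_bp}"
                f"\t{mk.allele_b}\t{mk.allele_a}\n"
            )
    with open(fam_path, "w") as fh:
        for iid in dataset.individuals:
            fh.write(f"{iid} {iid} 0 0 0 -9\n")
    n, m = dataset.genotypes.shape
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    if n:
        padded[:, :n] = _BED_ENCODE[dataset.genotypes.T]
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + _SNP_MAJOR)
        fh.write(packed.tobytes())
    return [bed_path, bim_path, fam_path]
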