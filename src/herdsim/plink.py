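"""PLINK 1.9 genotype file I/O (text .ped/.map and binary .bed/.bim/.fam).

The binary .bed uses the v1.0 magic (0x6c, 0x1b) with SNP-major layout
(third byte 0x01) and the standard 2-bit genotype codes; dosages count the
A1 allele as listed in the .bim file.  Alleles are written as "A" (A1, the
counted allele) and "B" (A2).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .qc import MISSING, GenotypeMatrix

MAGIC = bytes([0x6C, 0x1B, 0x01])
A1, A2 = "A", "B"
# 2-bit code -> dosage of A1: 00=2 copies, 10=het, 11=0 copies, 01=missing
CODE_TO_DOSAGE = {0b00: 2, 0b10: 1, 0b11: 0, 0b01: MISSING}
DOSAGE_TO_CODE = {v: k for k, v in CODE_TO_DOSAGE.items()}


class PlinkFormatError(ValueError):
    pass


def _fam_frame(g: GenotypeMatrix, pedigree=None) -> pd.DataFrame:
    ids = np.asarray(g.animal_ids)
    fam = pd.DataFrame({
        "fid": np.ones(len(ids), dtype=int),
        "iid": ids,
        "father": np.zeros(len(ids), dtype=int),
        "mother": np.zeros(len(ids), dtype=int),
        "sex": np.zeros(len(ids), dtype=int),
        "phenotype": np.full(len(ids), -9),
    })
    if pedigree is not None:
        pos = {int(a): i for i, a in enumerate(pedigree.ids)}
        rows = [pos.get(int(a)) for a in ids]
        fam["father"] = [int(pedigree.sire[r]) if r is not None else 0
                         for r in rows]
        fam["mother"] = [int(pedigree.dam[r]) if r is not None else 0
                         for r in rows]
        if pedigree.sex is not None:
            # PLINK: 1 = male, 2 = female
            fam["sex"] = [int(pedigree.sex[r]) + 1 if r is not None else 0
                          for r in rows]
    return fam


def _map_frame(g: GenotypeMatrix) -> pd.DataFrame:
    n = g.n_loci
    chrom = (np.asarray(g.chrom) if g.chrom is not None
             else np.ones(n, dtype=int))
    cm = np.asarray(g.pos_cm) if g.pos_cm is not None else np.zeros(n)
    bp = np.maximum(1, np.rint(cm * 1e6).astype(np.int64))
    if g.pos_cm is None:
        bp = np.arange(1, n + 1)
    return pd.DataFrame({
        "chrom": chrom, "locus_id": np.asarray(g.locus_ids),
        "pos_cm": cm, "pos_bp": bp,
    })


def write_plink(g: GenotypeMatrix, prefix, binary: bool = True,
                pedigree=None) -> list[Path]:
    """Write a .bed/.bim/.fam (binary=True) or .ped/.map file set."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fam = _fam_frame(g, pedigree)
    mp = _map_frame(g)
    if binary:
        bim = mp.copy()
        bim["a1"] = A1
        bim["a2"] = A2
        bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False,
                   index=False)
        fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False,
                   index=False)
        n = g.n_animals
        codes = np.empty((g.n_loci, n), dtype=np.uint8)
        d = g.dosages
        for dose, code in DOSAGE_TO_CODE.items():
            codes[(d == dose).T] = code
        stride = (n + 3) // 4
        packed = np.zeros((g.n_loci, stride * 4), dtype=np.uint8)
        packed[:, :n] = codes
        packed = packed.reshape(g.n_loci, stride, 4)
        byte = (packed[:, :, 0] | (packed[:, :, 1] << 2)
                | (packed[:, :, 2] << 4) | (packed[:, :, 3] << 6))
        with open(prefix.with_suffix(".bed"), "wb") as fh:
            fh.write(MAGIC)
            fh.write(byte.astype(np.uint8).tobytes())
        return [prefix.with_suffix(s) for s in (".bed", ".bim", ".fam")]

    mp.to_csv(prefix.with_suffix(".map"), sep="\t", header=False, index=False)
    allele = {2: f"{A1} {A1}", 1: f"{A1} {A2}", 0: f"{A2} {A2}",
              MISSING: "0 0"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(g.n_animals):
            front = " ".join(str(x) for x in fam.iloc[i])
            genos = " ".join(allele[int(v)] for v in g.dosages[i])
            fh.write(f"{front} {genos}\n" if genos else f"{front}\n")
    return [prefix.with_suffix(s) for s in (".ped", ".map")]


def _read_fam(path: Path) -> pd.DataFrame:
    fam = pd.read_csv(path, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex",
                             "phenotype"])
    if fam["iid"].duplicated().any():
        raise PlinkFormatError(f"duplicate animal IDs in {path}")
    return fam


def _read_bim(path: Path) -> pd.DataFrame:
    bim = pd.read_csv(path, sep=r"\s+", header=None,
                      names=["chrom", "locus_id", "pos_cm", "pos_bp",
                             "a1", "a2"])
    if bim["locus_id"].duplicated().any():
        raise PlinkFormatError(f"duplicate locus IDs in {path}")
    return bim


def read_plink(prefix) -> GenotypeMatrix:
    """Read a .bed/.bim/.fam or .ped/.map set into a GenotypeMatrix.

    Dosages count the A1 allele of the .bim (or the first allele symbol
    encountered for text input written by :func:`write_plink`).
    """
    prefix = Path(prefix)
    if prefix.with_suffix(".bed").exists():
        fam = _read_fam(prefix.with_suffix(".fam"))
        bim = _read_bim(prefix.with_suffix(".bim"))
        n, m = len(fam), len(bim)
        raw = prefix.with_suffix(".bed").read_bytes()
        if raw[:3] != MAGIC:
            raise PlinkFormatError(
                f"{prefix.with_suffix('.bed')}: bad magic bytes "
                f"{raw[:3]!r} (expected SNP-major PLINK v1 .bed)")
        stride = (n + 3) // 4
        body = np.frombuffer(raw[3:], dtype=np.uint8)
        if body.size != stride * m:
            raise PlinkFormatError(
                f"{prefix.with_suffix('.bed')}: truncated at byte "
                f"{3 + body.size}, expected {3 + stride * m} bytes")
        body = body.reshape(m, stride)
        codes = np.empty((m, stride * 4), dtype=np.uint8)
        for k in range(4):
            codes[:, k::4] = (body >> (2 * k)) & 0b11
        codes = codes[:, :n]
        dosages = np.full((m, n), MISSING, dtype=np.int8)
        for code, dose in CODE_TO_DOSAGE.items():
            dosages[codes == code] = dose
        return GenotypeMatrix(
            dosages=dosages.T,
            animal_ids=fam["iid"].to_numpy(),
            locus_ids=bim["locus_id"].to_numpy(),
            chrom=bim["chrom"].to_numpy(),
            pos_cm=bim["pos_cm"].to_numpy(float),
        )

    if not prefix.with_suffix(".ped").exists():
        raise PlinkFormatError(f"no .bed or .ped found for prefix {prefix}")
    mp = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None,
                     names=["chrom", "locus_id", "pos_cm", "pos_bp"])
    rows = []
    iids = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * len(mp):
                raise PlinkFormatError(
                    f"{prefix.with_suffix('.ped')}: expected "
                    f"{6 + 2 * len(mp)} fields, found {len(parts)}")
            iids.append(int(parts[1]))
            al = parts[6:]
            pairs = zip(al[0::2], al[1::2])
            rows.append([MISSING if a == "0" or b == "0"
                         else (a == A1) + (b == A1) for a, b in pairs])
    if len(set(iids)) != len(iids):
        raise PlinkFormatError(f"duplicate animal IDs in "
                               f"{prefix.with_suffix('.ped')}")
    return GenotypeMatrix(
        dosages=np.array(rows, dtype=np.int8),
        animal_ids=np.array(iids),
        locus_ids=mp["locus_id"].to_numpy(),
        chrom=mp["chrom"].to_numpy(),
        pos_cm=mp["pos_cm"].to_numpy(float),
    )
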