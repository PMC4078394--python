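"""PLINK 1 binary genotype IO (bed/bim/fam).

Implements the SNP-major 2-bit encoding directly: magic bytes 0x6c 0x1b
followed by 0x01 (SNP-major), then ceil(n/4) bytes per marker, two bits per
subject, least-significant pair first.  With the minor allele as A1 the codes
decode to minor-allele dosages as::

    00 -> 2 (homozygous A1)      10 -> 1 (heterozygous)
    01 -> missing                11 -> 0 (homozygous A2)

Round-trips are bit-exact, including missing genotypes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, MarkerInfo

__all__ = ["read_plink", "write_plink"]

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> dosage of A1 (minor) allele; 01 is the missing code
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0, MISSING: 1, 1: 2, 0: 3}


def write_plink(gm: GenotypeMatrix, prefix: str, a1: str = "A", a2: str = "B") -> None:
    """Write ``prefix.bed/.bim/.fam`` in SNP-major PLINK 1 binary format."""
    n, p = gm.n_subjects, gm.p_markers
    n_bytes = (n + 3) // 4
    codes = np.empty((p, n), dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[gm.raw.T == dosage] = code
    # pack 4 subjects per byte, low bit-pair first
    padded = np.zeros((p, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (padded.reshape(p, n_bytes, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())

    bim = pd.DataFrame(
        {
            "chrom": [m.chromosome for m in gm.markers],
            "id": [m.marker_id for m in gm.markers],
            "cM": 0.0,
            "bp": [m.bp_position for m in gm.markers],
            "A1": a1,
            "A2": a2,
        }
    )
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "FID": [f"F{i + 1}" for i in range(n)],
            "IID": [f"I{i + 1}" for i in range(n)],
            "PID": 0,
            "MID": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(f"{prefix}.fam", sep=" ", header=False, index=False)


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read ``prefix.bed/.bim/.fam`` into a :class:`GenotypeMatrix`."""
    bim = pd.read_csv(
        f"{prefix}.bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cM", "bp", "A1", "A2"],
        dtype={"chrom": str, "id": str},
    )
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None)
    n, p = len(fam), len(bim)
    n_bytes = (n + 3) // 4

    data = Path(f"{prefix}.bed").read_bytes()
    if data[:3] != _MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK 1 bed)")
    body = np.frombuffer(data[3:], dtype=np.uint8)
    if body.size != p * n_bytes:
        raise ValueError(f"{prefix}.bed: size mismatch for n={n}, p={p}")
    body = body.reshape(p, n_bytes)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = ((body[:, :, None] >> shifts) & 3).reshape(p, n_bytes * 4)[:, :n]
    raw = _CODE_TO_DOSAGE[codes].T  # (n, p)

    markers = []
    for j, row in enumerate(bim.itertuples()):
        col = raw[:, j]
        obs = col[col != MISSING]
        freq = float(obs.mean()) / 2.0 if obs.size else 0.0
        markers.append(
            MarkerInfo(
                marker_id=str(row.id),
                chromosome=str(row.chrom),
                bp_position=int(row.bp),
                maf=min(max(freq, 1e-12), 1.0 - freq) if obs.size else 1e-12,
            )
        )
    return GenotypeMatrix.from_raw(raw, markers=markers)
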