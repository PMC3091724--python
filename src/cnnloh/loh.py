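"""Paired per-SNP LOH calling with matched blood as the germline reference.

LOH is observable only at *informative* SNPs — those heterozygous in blood.
At an informative SNP, a homozygous call in the target tissue is LOH and a
heterozygous call is retention; a target no-call, or any uninformative SNP,
is undefined. No smoothing is applied here: segment-level structure is
derived downstream so each stage stays auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AA, AB, BB, NC, LOH, RETENTION, UNDEFINED


def informative_snps(blood: np.ndarray) -> np.ndarray:
    """Boolean mask of informative SNPs: blood call is AB."""
    return np.asarray(blood) == AB


@dataclass
class LohQC:
    """Per-call-column quality tallies."""

    n_informative: int
    n_loh: int
    n_retention: int
    n_target_nocall: int
    n_discordant_hom: int  # blood AA vs target BB or vice versa: call error, not LOH


def call_loh(blood: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, LohQC]:
    """Per-SNP LOH status of ``target`` against matched ``blood``.

    Returns ``(status, qc)`` where status is int8 per SNP: 1 = LOH,
    0 = retention, -1 = undefined. Discordant homozygotes (blood AA, target
    BB or the reverse) indicate genotyping error and are left undefined but
    tallied in the QC record.
    """
    blood = np.asarray(blood)
    target = np.asarray(target)
    if blood.shape != target.shape:
        raise ValueError(f"column length mismatch: {blood.shape} vs {target.shape}")
    status = np.full(blood.shape, UNDEFINED, dtype=np.int8)
    info = blood == AB
    status[info & ((target == AA) | (target == BB))] = LOH
    status[info & (target == AB)] = RETENTION
    discordant = (((blood == AA) & (target == BB)) | ((blood == BB) & (target == AA)))
    qc = LohQC(
        n_informative=int(info.sum()),
        n_loh=int((status == LOH).sum()),
        n_retention=int((status == RETENTION).sum()),
        n_target_nocall=int((info & (target == NC)).sum()),
        n_discordant_hom=int(discordant.sum()),
    )
    return status, qc


def call_loh_matrix(blood: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Vectorized :func:`call_loh` over a whole (n_snps, n_cases) cohort."""
    status, _ = call_loh(blood, target)
    return status
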