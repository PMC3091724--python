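"""Readers/writers and the domain data model.

All tabular inputs are tab-separated with one header line. Coordinates are
1-based inclusive internally (SNP-array annotation convention); BED export
converts to 0-based half-open. Genotypes are unphased and strandless:
``AA``/``AB``/``BB`` are relative to the array's allele labels, ``NC`` is a
no-call. Only autosomes (1-22) are admitted — sex chromosomes are excluded
from the coordinate system up front to avoid hemizygosity artifacts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Genotype call alphabet and its integer codes.
GENOTYPES = ("AA", "AB", "BB", "NC")
AA, AB, BB, NC = 0, 1, 2, 3
_GENO_CODE = {g: i for i, g in enumerate(GENOTYPES)}

#: LOH status codes (per SNP, per case).
RETENTION, LOH, UNDEFINED = 0, 1, -1

#: Copy-number groups derived from the five CN states.
LOSS, NEUTRAL, GAIN = 0, 1, 2
CN_GROUP_NAMES = ("loss", "neutral", "gain")

SNP_MAP_COLUMNS = ("snp_id", "chrom", "arm", "pos")
SEGMENT_COLUMNS = ("case_id", "chrom", "start", "end", "loh", "cn_group", "n_snps")


class ParseError(ValueError):
    """Raised when an input table violates its contract."""


def cn_group(state: int) -> int:
    """Map a CN state (0-4) to its group: ``<=1`` loss, ``2`` neutral, ``>=3`` gain."""
    if state <= 1:
        return LOSS
    if state == 2:
        return NEUTRAL
    return GAIN


def cn_group_array(states: np.ndarray) -> np.ndarray:
    """Vectorized :func:`cn_group`."""
    out = np.full(states.shape, NEUTRAL, dtype=np.int8)
    out[states <= 1] = LOSS
    out[states >= 3] = GAIN
    return out


def validate_snp_map(snp_map: pd.DataFrame) -> pd.DataFrame:
    """Check the SNP-map invariants, returning the (possibly re-sorted) map.

    Invariants: autosomal chromosomes only, positions strictly increasing
    within each chromosome, unique snp_ids, and all p-arm positions below all
    q-arm positions on each chromosome.
    """
    missing = set(SNP_MAP_COLUMNS) - set(snp_map.columns)
    if missing:
        raise ParseError(f"SNP map missing columns: {sorted(missing)}")
    chrom_raw = snp_map["chrom"].astype(str)
    bad = ~chrom_raw.str.fullmatch(r"\d+")
    if bad.any():
        offender = chrom_raw[bad].iloc[0]
        raise ParseError(f"non-autosomal chromosome {offender!r} in SNP map (X/Y excluded)")
    snp_map = snp_map.assign(chrom=chrom_raw.astype(np.int64), pos=snp_map["pos"].astype(np.int64))
    if not snp_map["chrom"].between(1, 22).all():
        raise ParseError("chromosomes must be in 1..22")
    if snp_map["snp_id"].duplicated().any():
        dup = snp_map.loc[snp_map["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ParseError(f"duplicate snp_id {dup!r}")
    if not snp_map["arm"].isin(["p", "q"]).all():
        raise ParseError("arm must be 'p' or 'q'")
    sorted_map = snp_map.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if not sorted_map[["chrom", "pos"]].equals(snp_map[["chrom", "pos"]].reset_index(drop=True)):
        logger.warning("SNP map was not sorted by (chrom, pos); sorting")
    snp_map = sorted_map
    for chrom, sub in snp_map.groupby("chrom"):
        pos = sub["pos"].to_numpy()
        if (np.diff(pos) <= 0).any():
            raise ParseError(f"positions not strictly increasing on chromosome {chrom}")
        p_pos = sub.loc[sub["arm"] == "p", "pos"]
        q_pos = sub.loc[sub["arm"] == "q", "pos"]
        if len(p_pos) and len(q_pos) and p_pos.max() >= q_pos.min():
            raise ParseError(f"p/q arm positions interleave on chromosome {chrom}")
    return snp_map


def read_snp_map(path) -> pd.DataFrame:
    """Read an ordered autosomal SNP map (snp_id, chrom, arm, pos)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "arm": str})
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise ParseError(f"cannot parse SNP map {path}: {exc}") from exc
    return validate_snp_map(df)


def write_snp_map(snp_map: pd.DataFrame, path) -> None:
    snp_map.to_csv(path, sep="\t", index=False)


def encode_genotypes(calls: pd.DataFrame) -> np.ndarray:
    """Encode a string genotype matrix into int8 codes (AA=0, AB=1, BB=2, NC=3)."""
    arr = calls.to_numpy()
    flat = pd.Series(arr.ravel())
    unknown = ~flat.isin(GENOTYPES)
    if unknown.any():
        raise ParseError(f"unknown genotype token {flat[unknown].iloc[0]!r}")
    codes = flat.map(_GENO_CODE).to_numpy(dtype=np.int8)
    return codes.reshape(arr.shape)


def decode_genotypes(codes: np.ndarray, index, columns) -> pd.DataFrame:
    lut = np.asarray(GENOTYPES, dtype=object)
    return pd.DataFrame(lut[codes], index=index, columns=columns)


def read_genotype_matrix(path, snp_map: pd.DataFrame) -> pd.DataFrame:
    """Read a genotype call matrix (rows = SNPs, columns = samples).

    Rows are re-ordered to match ``snp_map``; SNPs absent from the file are
    flagged and filled with ``NC``. Rows whose snp_id is not in the map are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    unknown = df.index.difference(snp_map["snp_id"])
    if len(unknown):
        raise ParseError(f"genotype matrix rows not in SNP map: {list(unknown[:5])}")
    encode_genotypes(df)  # validate tokens
    missing = snp_map["snp_id"][~snp_map["snp_id"].isin(df.index)]
    if len(missing):
        logger.warning("%d SNPs missing from %s; filled with NC", len(missing), path)
    out = df.reindex(snp_map["snp_id"]).fillna("NC")
    out.index.name = df.index.name or "snp_id"
    return out


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write any SNP-indexed matrix (genotypes, log-ratios, states) as TSV."""
    df.to_csv(path, sep="\t", index=True)


def read_numeric_matrix(path, snp_map: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a float matrix (e.g. per-SNP log2 ratios), optionally map-aligned."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.astype(float)
    if snp_map is not None:
        unknown = df.index.difference(snp_map["snp_id"])
        if len(unknown):
            raise ParseError(f"matrix rows not in SNP map: {list(unknown[:5])}")
        df = df.reindex(snp_map["snp_id"])
    return df


def read_gene_table(path) -> pd.DataFrame:
    """Read a probe-set annotation table (probeset_id, gene_symbol, chrom, start, end)."""
    df = pd.read_csv(path, sep="\t", dtype={"probeset_id": str, "gene_symbol": str})
    required = {"probeset_id", "gene_symbol", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"gene table missing columns: {sorted(missing)}")
    if (df["start"] > df["end"]).any():
        raise ParseError("gene region start > end")
    if df["probeset_id"].duplicated().any():
        raise ParseError("duplicate probeset_id in gene table")
    return df


def validate_segments(segments: pd.DataFrame) -> pd.DataFrame:
    missing = set(SEGMENT_COLUMNS) - set(segments.columns)
    if missing:
        raise ParseError(f"segment table missing columns: {sorted(missing)}")
    if (segments["start"] > segments["end"]).any():
        raise ParseError("segment start > end")
    if not segments["cn_group"].isin(CN_GROUP_NAMES).all():
        raise ParseError("cn_group must be loss/neutral/gain")
    for (_, _), sub in segments.groupby(["case_id", "chrom"]):
        s = sub.sort_values("start")
        if (s["start"].to_numpy()[1:] <= s["end"].to_numpy()[:-1]).any():
            raise ParseError("overlapping segments within one case/chromosome")
    return segments


def write_segments_bed(segments: pd.DataFrame, path) -> None:
    """Write segments as 6-column BED.

    name = ``{LOH|RET}|{cn_group}``, score = number of informative SNPs,
    coordinates converted from 1-based inclusive to 0-based half-open.
    """
    segments = validate_segments(segments)
    with open(path, "w") as fh:
        for row in segments.itertuples(index=False):
            name = f"{'LOH' if row.loh else 'RET'}|{row.cn_group}"
            fh.write(
                f"chr{row.chrom}\t{row.start - 1}\t{row.end}\t{name}\t{row.n_snps}\t.\n"
            )


def read_segments_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"case_id": str, "cn_group": str})
    df["loh"] = df["loh"].astype(bool)
    return validate_segments(df)


def write_segments_tsv(segments: pd.DataFrame, path) -> None:
    validate_segments(segments).to_csv(path, sep="\t", index=False)
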