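"""Copy-number preprocessing: SEG calls -> blocks -> matrix -> PCA -> [0,1].

Segmented copy-number calls (TCGA level-3 style SEG text: sample,
chromosome, start, end, log2 tumor/normal ratio) are converted into a
sample-by-block matrix per chromosome, where a *block* is a maximal genomic
interval on which every sample's copy-number value is constant — block
boundaries are the union of all samples' segment breakpoints.  Chromosome
matrices are concatenated genome-wide (autosomes only), reduced to the top
principal components, and min-max normalised per dimension to [0, 1], the
range the clustering bandwidth h = 1 assumes.

Coordinate convention: SEG rows are read as 1-based with inclusive ends
(the dominant TCGA dialect); blocks are handled internally as half-open
0-based intervals and reported back in the 1-based inclusive convention.
Genomic positions not covered by any call in a sample are taken as log2
ratio 0 (diploid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SEG_COLUMNS",
    "BlockMatrix",
    "read_seg",
    "write_seg",
    "build_blocks",
    "concatenate_chromosomes",
    "normalize_unit_range",
    "pca_top",
]

logger = logging.getLogger(__name__)

SEG_COLUMNS = ["sample", "chromosome", "start", "end", "log2_ratio"]
_HEADER_ALIASES = {
    "sample": "sample", "id": "sample", "sample_id": "sample",
    "chromosome": "chromosome", "chrom": "chromosome", "chr": "chromosome",
    "start": "start", "loc.start": "start",
    "end": "end", "loc.end": "end", "stop": "end",
    "segment_mean": "log2_ratio", "seg.mean": "log2_ratio", "log2_ratio": "log2_ratio",
    "num_probes": "num_probes", "num.mark": "num_probes",
}
_AUTOSOMES = {str(i) for i in range(1, 23)}


@dataclass
class BlockMatrix:
    """Per-chromosome sample-by-block matrix of log2 copy-number ratios.

    ``boundaries`` are half-open 0-based (start, end) intervals tiling the
    covered region; ``values`` has one row per sample (sorted sample ids as
    the index) and one column per block.
    """

    chromosome: int
    values: pd.DataFrame
    boundaries: list[tuple[int, int]]

    @property
    def n_blocks(self) -> int:
        return len(self.boundaries)


def read_seg(path) -> pd.DataFrame:
    """Read a SEG-style tab-delimited file into a tidy calls table.

    Accepts the common TCGA header variants (Sample/ID, Chromosome,
    Start/End, optional Num_Probes, Segment_Mean).  Non-autosomal rows are
    dropped with a logged count; chromosome labels may carry a ``chr``
    prefix.  Raises ``ValueError`` with 1-based line numbers for rows whose
    coordinates or segment means do not parse.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = {c: _HEADER_ALIASES.get(c.strip().lower()) for c in raw.columns}
    raw = raw.rename(columns={c: t for c, t in cols.items() if t})
    missing = [c for c in SEG_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"SEG file {path} is missing required columns: {missing}")

    chrom = raw["chromosome"].str.strip().str.replace("^chr", "", regex=True)
    autosomal = chrom.isin(_AUTOSOMES)
    n_dropped = int((~autosomal).sum())
    if n_dropped:
        logger.info("dropped %d non-autosomal rows from %s", n_dropped, path)
    df = raw[autosomal].copy()
    df["chromosome"] = chrom[autosomal].astype(int)

    bad_lines: list[int] = []
    for col in ("start", "end", "log2_ratio"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad_lines.extend((df.index[parsed.isna()] + 2).tolist())  # +2: header + 1-based
        df[col] = parsed
    if bad_lines:
        raise ValueError(f"unparseable rows in {path} at lines {sorted(set(bad_lines))}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] > df["end"]).any():
        bad = df.index[df["start"] > df["end"]][0] + 2
        raise ValueError(f"segment with start > end in {path} at line {bad}")
    keep = [c for c in SEG_COLUMNS if c in df.columns]
    return df[keep].reset_index(drop=True)


def write_seg(calls: pd.DataFrame, path) -> None:
    """Write a calls table back to SEG-style text (round-trips read_seg)."""
    out = calls.rename(
        columns={"sample": "Sample", "chromosome": "Chromosome", "start": "Start",
                 "end": "End", "log2_ratio": "Segment_Mean"}
    )
    out.to_csv(path, sep="\t", index=False)


def build_blocks(calls: pd.DataFrame, chromosome: int) -> BlockMatrix:
    """Decompose one chromosome's calls into constant-copy-number blocks.

    Block boundaries are the sorted union of every sample's segment
    breakpoints, so no sample's value changes strictly inside a block;
    blocks covered by no sample at all are dropped.  A sample's entry over a
    block is its log2 ratio there, or 0 (diploid) where it has no call.
    Overlapping segments within one sample are rejected by name.
    """
    sub = calls[calls["chromosome"] == chromosome]
    samples = sorted(sub["sample"].unique())
    if not len(sub):
        return BlockMatrix(chromosome=chromosome,
                           values=pd.DataFrame(index=samples), boundaries=[])
    # to half-open 0-based: [start-1, end)
    segs: dict[str, list[tuple[int, int, float]]] = {s: [] for s in samples}
    for row in sub.itertuples(index=False):
        segs[row.sample].append((int(row.start) - 1, int(row.end), float(row.log2_ratio)))
    cuts: set[int] = set()
    for s, lst in segs.items():
        lst.sort()
        for (a0, b0, _), (a1, _, _) in zip(lst, lst[1:]):
            if a1 < b0:
                raise ValueError(
                    f"overlapping segments for sample {s!r} on chromosome {chromosome}"
                )
        for a, b, _ in lst:
            cuts.update((a, b))
    bounds = sorted(cuts)
    blocks = [(a, b) for a, b in zip(bounds, bounds[1:])]
    covered = [
        any(a >= sa and b <= sb for lst in segs.values() for sa, sb, _ in lst)
        for a, b in blocks
    ]
    blocks = [blk for blk, c in zip(blocks, covered) if c]
    M = np.zeros((len(samples), len(blocks)))
    for i, s in enumerate(samples):
        for sa, sb, val in segs[s]:
            for j, (a, b) in enumerate(blocks):
                if a >= sa and b <= sb:
                    M[i, j] = val
    values = pd.DataFrame(M, index=samples,
                          columns=[f"chr{chromosome}:{a + 1}-{b}" for a, b in blocks])
    return BlockMatrix(chromosome=chromosome, values=values, boundaries=blocks)


def concatenate_chromosomes(
    blocks: list[BlockMatrix],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenate per-chromosome block matrices into one genome-wide matrix.

    Columns are ordered chromosome-major, block-minor.  The sample set is
    the union across chromosomes; samples absent from a chromosome get zero
    (diploid) rows there, with a logged count.  Also returns per-column
    metadata (chromosome, start, end — 1-based inclusive) for mapping
    amplified blocks back to genomic coordinates.
    """
    blocks = sorted(blocks, key=lambda b: b.chromosome)
    samples = sorted({s for b in blocks for s in b.values.index})
    parts, meta_rows = [], []
    for b in blocks:
        absent = len(samples) - len(b.values.index)
        if absent:
            logger.info("chromosome %d: %d samples absent, filled with 0", b.chromosome, absent)
        parts.append(b.values.reindex(samples, fill_value=0.0))
        meta_rows.extend(
            {"chromosome": b.chromosome, "start": a + 1, "end": e}
            for a, e in b.boundaries
        )
    matrix = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=samples)
    meta = pd.DataFrame(meta_rows, columns=["chromosome", "start", "end"])
    meta.index = matrix.columns
    return matrix, meta


def normalize_unit_range(M):
    """Affinely map each column to [0, 1] (min -> 0, max -> 1).

    Constant columns are mapped to 0: a feature without variation carries no
    clustering signal.  Accepts an ndarray or DataFrame; the type and labels
    are preserved.  Idempotent.
    """
    values = np.asarray(M, dtype=float)
    lo = values.min(axis=0)
    span = values.max(axis=0) - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (values - lo) / span
    out[:, span == 0] = 0.0
    if isinstance(M, pd.DataFrame):
        return pd.DataFrame(out, index=M.index, columns=M.columns)
    return out


def pca_top(M, n_components: int = 10):
    """Scores on the top principal components of the column-centered matrix.

    Reducing to ~10 dimensions increases point density, which mode-seeking
    clustering needs to identify representatives.  Components use a
    deterministic sign convention (the largest-magnitude loading of each
    component is positive).  Returns fewer components, with a log message,
    when the matrix rank is below ``n_components``.
    """
    values = np.asarray(M, dtype=float)
    if values.shape[0] <= 1:
        raise ValueError("PCA needs more than one sample")
    centered = values - values.mean(axis=0)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    tol = max(centered.shape) * np.finfo(float).eps * (S[0] if len(S) else 0.0)
    rank = int((S > tol).sum())
    n_keep = min(n_components, rank)
    if n_keep < n_components:
        logger.info("rank %d < %d requested components; returning %d", rank, n_components, n_keep)
    # sign convention: flip so each component's largest-|loading| is positive
    for j in range(n_keep):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    scores = U[:, :n_keep] * S[:n_keep]
    if isinstance(M, pd.DataFrame):
        return pd.DataFrame(scores, index=M.index,
                            columns=[f"PC{j + 1}" for j in range(n_keep)])
    return scores
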