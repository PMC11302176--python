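"""Population analysis of element copies against a family consensus.

Copies are aligned individually to the family consensus (Water-style
local alignment, gap open 50 / gap extend 0.1 — heavy gap penalties keep
near-identical copies colinear), and the alignments are collapsed into a
variant table in consensus coordinates: insertions in copies are ignored
(they have no consensus coordinate), deletions are missing data, sites
are retained at minor-allele frequency >= 1% among non-missing calls and
a per-site missing-data cutoff of 90%.  The table feeds PCA (subfamily
structure) and pairwise SNP counts (input to the Mantel test).

Family consensus sequences are built from 30 randomly sampled copies via
a star multiple alignment and column majority.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .align import GAP, PairwiseAlignment, local_align
from .models import PCAResult, VariantTable

logger = logging.getLogger(__name__)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE = "ACGT"

COPY_GAP_OPEN = 50.0
COPY_GAP_EXTEND = 0.1
MIN_COPY_COVERAGE = 0.30  # of consensus length; below this a copy is dropped


def align_copy_to_consensus(
    copy_seq: str,
    consensus: str,
    gap_open: float = COPY_GAP_OPEN,
    gap_extend: float = COPY_GAP_EXTEND,
) -> PairwiseAlignment:
    """Local alignment of one copy (query) against the consensus (target)."""
    return local_align(copy_seq, consensus, gap_open=gap_open, gap_extend=gap_extend)


def calls_from_alignment(
    aln: PairwiseAlignment, consensus_length: int
) -> np.ndarray:
    """Per-consensus-position base codes for one copy.

    Returns an int8 array of length ``consensus_length``: 0..3 = A/C/G/T,
    -1 = missing (deleted in the copy, ambiguous, or outside the aligned
    region).  Copy bases in insertions are discarded.
    """
    calls = np.full(consensus_length, -1, dtype=np.int8)
    pos_cons = aln.start_b
    for x, y in zip(aln.aligned_a.upper(), aln.aligned_b.upper()):
        if y == GAP:  # insertion in the copy: no consensus coordinate
            continue
        if x != GAP:
            calls[pos_cons] = _CODE.get(x, -1)
        pos_cons += 1
    return calls


def call_variants(
    copies: dict[str, str],
    consensus: str,
    maf: float = 0.01,
    missing_cutoff: float = 0.90,
    gap_open: float = COPY_GAP_OPEN,
    gap_extend: float = COPY_GAP_EXTEND,
    consensus_id: str = "consensus",
) -> VariantTable:
    """Build the copies x sites variant table for one family.

    ``copies`` maps copy id -> element sequence (5'->3' orientation).
    Copies aligning over less than 30% of the consensus are dropped with
    a logged warning.
    """
    if not consensus:
        raise ValueError("empty consensus")
    if not copies:
        raise ValueError("no copies")
    L = len(consensus)
    kept_ids: list[str] = []
    call_rows: list[np.ndarray] = []
    for copy_id, seq in copies.items():
        try:
            aln = align_copy_to_consensus(seq, consensus, gap_open, gap_extend)
        except ValueError:
            logger.warning("copy %s failed to align; dropped", copy_id)
            continue
        calls = calls_from_alignment(aln, L)
        covered = int((calls >= 0).sum())
        # coverage counts aligned consensus columns (incl. mismatches)
        aligned_cols = sum(1 for y in aln.aligned_b if y != GAP)
        if aligned_cols < MIN_COPY_COVERAGE * L:
            logger.warning(
                "copy %s aligns over %d/%d bp of the consensus; dropped",
                copy_id,
                aligned_cols,
                L,
            )
            continue
        kept_ids.append(copy_id)
        call_rows.append(calls)
        del covered
    if not call_rows:
        raise ValueError("no copy aligned to the consensus")
    calls = np.vstack(call_rows)  # n x L
    n = calls.shape[0]
    ref_codes = np.array([_CODE.get(b, -1) for b in consensus.upper()], dtype=np.int8)

    positions: list[int] = []
    refs: list[str] = []
    alts: list[list[str]] = []
    geno_cols: list[np.ndarray] = []
    for j in range(L):
        col = calls[:, j]
        obs = col[col >= 0]
        if obs.size == 0:
            continue
        missing_frac = 1.0 - obs.size / n
        if missing_frac > missing_cutoff:
            continue
        counts = np.bincount(obs, minlength=4)
        if counts.max() == obs.size:
            # monomorphic among observed calls
            continue
        site_maf = 1.0 - counts.max() / obs.size
        if site_maf < maf:
            continue
        ref_code = ref_codes[j]
        if ref_code < 0:
            continue
        alt_codes = [
            c
            for c in np.argsort(-counts, kind="stable")
            if counts[c] > 0 and c != ref_code
        ]
        code_map = np.full(4, -1, dtype=np.int8)
        code_map[ref_code] = 0
        for k, c in enumerate(alt_codes, start=1):
            code_map[c] = k
        g = np.where(col >= 0, code_map[np.clip(col, 0, 3)], -1).astype(np.int8)
        positions.append(j)
        refs.append(_BASE[ref_code])
        alts.append([_BASE[c] for c in alt_codes])
        geno_cols.append(g)

    genotypes = (
        np.stack(geno_cols, axis=1) if geno_cols else np.zeros((n, 0), dtype=np.int8)
    )
    table = VariantTable(
        consensus_id=consensus_id,
        positions=np.array(positions, dtype=np.int64),
        ref_alleles=refs,
        alt_alleles=alts,
        genotypes=genotypes,
        copy_ids=kept_ids,
        maf=maf,
        missing_cutoff=missing_cutoff,
    )
    table.validate_site_bounds()
    return table


def star_msa(
    seqs: dict[str, str], center_id: Optional[str] = None
) -> tuple[list[str], list[list[str]]]:
    """Star multiple alignment: every sequence pairwise-aligned to a centre.

    Returns ``(ids, columns)`` where ``columns[k]`` lists one symbol per
    sequence (base or ``-``).  The centre defaults to the longest input.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ids = list(seqs)
    if center_id is None:
        center_id = max(ids, key=lambda i: (len(seqs[i]), i))
    center = seqs[center_id]
    Lc = len(center)
    others = [i for i in ids if i != center_id]
    # per sequence: base at each centre position; insertions keyed by
    # (centre position before which they occur, running index)
    base_at = {i: np.full(Lc, -2, dtype=np.int8) for i in others}  # -2 gap
    insertions: dict[tuple[int, int], dict[str, str]] = defaultdict(dict)
    for i in others:
        aln = local_align(seqs[i], center, gap_open=COPY_GAP_OPEN, gap_extend=COPY_GAP_EXTEND)
        pos_c = aln.start_b
        ins_idx = 0
        for x, y in zip(aln.aligned_a.upper(), aln.aligned_b.upper()):
            if y == GAP:
                insertions[(pos_c, ins_idx)][i] = x
                ins_idx += 1
                continue
            ins_idx = 0
            if x != GAP and x in _CODE:
                base_at[i][pos_c] = _CODE[x]
            pos_c += 1
    ordered_ids = [center_id] + others
    columns: list[list[str]] = []
    max_ins = defaultdict(int)
    for (p, k), _ in insertions.items():
        max_ins[p] = max(max_ins[p], k + 1)
    for p in range(Lc + 1):
        for k in range(max_ins.get(p, 0)):
            col = [GAP]
            ins = insertions.get((p, k), {})
            col += [ins.get(i, GAP) for i in others]
            columns.append(col)
        if p < Lc:
            col = [center[p].upper()]
            for i in others:
                b = base_at[i][p]
                col.append(_BASE[b] if b >= 0 else GAP)
            columns.append(col)
    return ordered_ids, columns


def consensus_from_columns(columns: list[list[str]]) -> str:
    """Column-majority consensus; majority-gap columns dropped, base ties
    broken alphabetically."""
    out = []
    for col in columns:
        counts = Counter(col)
        gap_n = counts.pop(GAP, 0)
        if not counts:
            continue
        best_n = max(counts.values())
        if gap_n > best_n:
            continue
        out.append(min(b for b, c in counts.items() if c == best_n))
    return "".join(out)


def build_consensus(
    copies: dict[str, str],
    sample_n: int = 30,
    seed: int = 0,
    msa: str = "star",
) -> str:
    """Family consensus from ``sample_n`` randomly sampled copies.

    Sampling is without replacement and seeded; the multiple alignment is
    the built-in star MSA (``msa="star"``) or an external ``mafft``
    binary (``msa="mafft"``), and the consensus is the column majority.
    """
    if len(copies) < 2:
        raise ValueError("need at least 2 copies to build a consensus")
    rng = np.random.default_rng(seed)
    ids = sorted(copies)
    take = min(sample_n, len(ids))
    sampled = {i: copies[i] for i in rng.choice(ids, size=take, replace=False)}
    if msa == "mafft":
        columns = _mafft_columns(sampled)
    else:
        _, columns = star_msa(sampled)
    return consensus_from_columns(columns)


def _mafft_columns(seqs: dict[str, str]) -> list[list[str]]:
    import subprocess
    import tempfile

    from Bio import SeqIO

    with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as fh:
        for k, v in seqs.items():
            fh.write(f">{k}\n{v}\n")
        path = fh.name
    res = subprocess.run(
        ["mafft", "--auto", "--quiet", path], capture_output=True, text=True, check=True
    )
    rows = []
    from io import StringIO

    for rec in SeqIO.parse(StringIO(res.stdout), "fasta"):
        rows.append(str(rec.seq).upper())
    return [list(col) for col in zip(*rows)]


def run_pca(table: VariantTable, n_components: int = 10) -> PCAResult:
    """PCA of the numerically encoded genotype matrix.

    Missing genotypes are mean-imputed per site; the matrix is centred
    and decomposed with a deterministic full SVD.  Component signs follow
    scikit-learn's convention (largest absolute loading positive).
    """
    if table.n_copies < 2 or table.n_sites < 1:
        raise ValueError("need >= 2 copies and >= 1 site")
    X = table.genotypes.astype(float)
    X[X == VariantTable.MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    if np.allclose(X.var(axis=0).sum(), 0):
        raise ValueError("degenerate input: zero total variance")
    k = min(n_components, table.n_copies - 1, table.n_sites)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(X)
    return PCAResult(
        coordinates=coords,
        explained_variance=pca.explained_variance_,
        component_loadings=pca.components_.T,
        copy_ids=list(table.copy_ids),
    )


def pairwise_snp_distance(table: VariantTable) -> np.ndarray:
    """Copies x copies matrix of pairwise SNP counts.

    Entry (i, j) counts sites where both copies have non-missing calls
    that differ (the pairwise-deletion convention of ape's dist.gene).
    """
    if table.n_copies == 0:
        raise ValueError("empty table")
    g = table.genotypes
    n = table.n_copies
    dist = np.zeros((n, n), dtype=np.int64)
    present = g != VariantTable.MISSING
    for i in range(n):
        both = present[i] & present
        diff = (g[i] != g) & both
        dist[i] = diff.sum(axis=1)
    np.fill_diagonal(dist, 0)
    return dist
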