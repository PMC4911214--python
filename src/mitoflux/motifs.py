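"""Rank-based cis-motif enrichment on expression-ordered gene lists.

The question asked here: do genes whose promoters contain a candidate motif
sit unusually high (or low) in a list of genes ordered by their transcriptional
response?  The procedure is exhaustive word-based motif discovery in the
motifADE style: enumerate every ungapped DNA word in a length range (plus
9-mers with a single interior wildcard), scan each gene's TSS-flanking
sequence for presence on either strand, and compare the ranks of motif-bearing
vs motif-free genes with a two-sided Mann-Whitney U test, Bonferroni-adjusted
for the number of motifs tested.  The effect size is the normalized shift of
the median rank of motif-bearing genes away from the list midpoint
(delta-median; negative = concentrated at the upregulated end).

Masked positions (repeats, non-conserved bases) are represented as ``N`` in
the promoter sequence and never match anything — including a wildcard in a
gapped motif — so repeat content cannot create false presence calls.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

logger = logging.getLogger(__name__)

#: IUPAC degenerate nucleotide codes -> the set of concrete bases they match.
#: ``N`` in a *motif* is a gap wildcard (matches any concrete base); ``N`` in a
#: *sequence* is a masked position and matches nothing.
IUPAC_CODES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_BASES = "ACGT"


def revcomp(pattern: str) -> str:
    """Reverse complement of a motif or sequence (IUPAC-aware)."""
    return pattern.translate(_COMPLEMENT)[::-1]


def canonical(pattern: str) -> str:
    """Strand-canonical form: lexicographic min of a motif and its reverse
    complement, so both strands collapse to one representative."""
    rc = revcomp(pattern)
    return pattern if pattern <= rc else rc


def iupac_match(base: str, code: str) -> bool:
    """Does a concrete (or masked) sequence base satisfy an IUPAC motif code?

    A masked base ``N`` in the sequence matches nothing.
    """
    if code not in IUPAC_CODES:
        raise ValueError(f"invalid IUPAC code {code!r}")
    if base == "N":
        return False
    return base in IUPAC_CODES[code]


@dataclass
class PromoterSet:
    """Per-gene TSS-flanking sequence, uppercase over {A,C,G,T,N}."""

    sequences: dict[str, str]
    half_width: int | None = None

    def __post_init__(self) -> None:
        for gene, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty promoter sequence for {gene}")
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValueError(f"invalid characters {bad} in promoter {gene}")

    def __len__(self) -> int:
        return len(self.sequences)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=gene, description="")
            for gene, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path, half_width: int | None = None) -> "PromoterSet":
        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")
        }
        if not seqs:
            raise ValueError(f"no FASTA records in {path}")
        return cls(seqs, half_width=half_width)


# ---------------------------------------------------------------------------
# motif enumeration
# ---------------------------------------------------------------------------

def enumerate_motifs(
    min_len: int = 6,
    max_len: int = 8,
    include_gapped9: bool = False,
    canonicalize: bool = False,
) -> list[str]:
    """Enumerate all candidate motif words.

    Every ungapped word over {A,C,G,T} of each length in [min_len, max_len];
    optionally all 9-mers carrying a single interior ``N`` gap (one N at each
    of the 7 interior positions, concrete flanks).  With ``canonicalize`` each
    word is replaced by its strand-canonical form and duplicates are removed
    (order of first appearance is kept).
    """
    if not 1 <= min_len <= max_len:
        raise ValueError("need 1 <= min_len <= max_len")
    words: list[str] = []
    for k in range(min_len, max_len + 1):
        words.extend("".join(t) for t in itertools.product(_BASES, repeat=k))
    if include_gapped9:
        for gap in range(1, 8):
            for t in itertools.product(_BASES, repeat=8):
                words.append("".join(t[:gap]) + "N" + "".join(t[gap:]))
    if canonicalize:
        seen: dict[str, None] = {}
        for w in words:
            seen.setdefault(canonical(w), None)
        words = list(seen)
    return words


# ---------------------------------------------------------------------------
# promoter scanning
# ---------------------------------------------------------------------------

def _pattern_regex(pattern: str) -> re.Pattern:
    parts = []
    for code in pattern:
        if code not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC code {code!r} in motif {pattern!r}")
        bases = IUPAC_CODES[code]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def scan_presence(
    promoters: PromoterSet,
    motif: str,
    bidirectional: bool = True,
) -> set[str]:
    """Gene ids whose promoter contains >= 1 match of the motif.

    Matching slides over every offset; masked ``N`` positions in the sequence
    fail matching (the regex classes contain concrete bases only).  In
    bidirectional mode the reverse complement of the motif is also tried.
    """
    patterns = [_pattern_regex(motif)]
    if bidirectional:
        rc = revcomp(motif)
        if rc != motif:
            patterns.append(_pattern_regex(rc))
    hits = set()
    for gene, seq in promoters.sequences.items():
        if any(p.search(seq) for p in patterns):
            hits.add(gene)
    return hits


def kmer_presence_index(
    promoters: PromoterSet,
    k: int,
    bidirectional: bool = True,
) -> dict[str, set[str]]:
    """Index word -> set of genes containing it, for bulk exhaustive scans.

    In bidirectional mode keys are strand-canonical words, so a lookup with
    ``canonical(motif)`` answers presence on either strand.  Windows touching
    a masked base are skipped.
    """
    canon_cache: dict[str, str] = {}
    index: dict[str, set[str]] = {}
    for gene, seq in promoters.sequences.items():
        words = set()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" in w:
                continue
            if bidirectional:
                cw = canon_cache.get(w)
                if cw is None:
                    cw = canonical(w)
                    canon_cache[w] = cw
                words.add(cw)
            else:
                words.add(w)
        for w in words:
            index.setdefault(w, set()).add(gene)
    return index


def gapped9_presence_index(
    promoters: PromoterSet,
    bidirectional: bool = True,
) -> dict[str, set[str]]:
    """Presence index for single-gap 9-mers (one interior N, concrete flanks).

    Keys are the full 9-character motif strings (canonical in bidirectional
    mode).  A window containing any masked base is skipped entirely: the gap
    wildcard matches concrete bases only.
    """
    canon_cache: dict[str, str] = {}
    index: dict[str, set[str]] = {}
    for gene, seq in promoters.sequences.items():
        words = set()
        for i in range(len(seq) - 8):
            w = seq[i : i + 9]
            if "N" in w:
                continue
            for gap in range(1, 8):
                gw = w[:gap] + "N" + w[gap + 1 :]
                if bidirectional:
                    cw = canon_cache.get(gw)
                    if cw is None:
                        cw = canonical(gw)
                        canon_cache[gw] = cw
                    words.add(cw)
                else:
                    words.add(gw)
        for w in words:
            index.setdefault(w, set()).add(gene)
    return index


# ---------------------------------------------------------------------------
# enrichment statistics
# ---------------------------------------------------------------------------

def motif_mwu(
    ranked: pd.DataFrame,
    with_set: Iterable[str],
    exact_threshold: int = 8,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on ranks of motif-bearing vs motif-free genes.

    ``ranked`` is a rank_genes output (columns ``gene_id`` and ``rank``).
    The exact null distribution is used when the smaller group has at most
    ``exact_threshold`` members; otherwise the normal approximation with
    continuity correction (ranks are distinct, so no tie correction is
    needed).  An empty or complete with-set is untestable and reported as
    (nan, 1.0).
    """
    with_set = set(with_set)
    extra = with_set - set(ranked["gene_id"])
    if extra:
        raise ValueError(f"with_set contains unranked genes: {sorted(extra)[:5]}")
    mask = ranked["gene_id"].isin(with_set).to_numpy()
    m = int(mask.sum())
    n_total = len(ranked)
    if m == 0 or m == n_total:
        logger.warning("motif present in %d of %d genes: untestable", m, n_total)
        return float("nan"), 1.0
    ranks = ranked["rank"].to_numpy(dtype=float)
    method = "exact" if min(m, n_total - m) <= exact_threshold else "asymptotic"
    res = stats.mannwhitneyu(
        ranks[mask], ranks[~mask], alternative="two-sided", method=method
    )
    return float(res.statistic), float(res.pvalue)


def delta_median(ranked: pd.DataFrame, with_set: Iterable[str]) -> float:
    """Normalized shift of the median rank of motif-bearing genes.

    (median rank - (N + 1)/2) / N, in [-0.5, 0.5]; negative means the motif's
    genes concentrate at the top (most-upregulated) end of the list.
    """
    with_set = set(with_set)
    mask = ranked["gene_id"].isin(with_set).to_numpy()
    if not mask.any():
        raise ValueError("with_set is empty or disjoint from the ranked list")
    n_total = len(ranked)
    med = float(np.median(ranked["rank"].to_numpy(dtype=float)[mask]))
    return (med - (n_total + 1) / 2.0) / n_total


def adjust_multiplicity(p_raw, n_motifs_tested: int):
    """Bonferroni adjustment over the number of motifs tested, capped at 1."""
    p = np.asarray(p_raw, dtype=float)
    if n_motifs_tested < p.size and n_motifs_tested < 1:
        raise ValueError("n_motifs_tested must be >= 1")
    adj = np.minimum(1.0, p * n_motifs_tested)
    return float(adj) if np.isscalar(p_raw) else adj


def consensus_binomial(
    promoters: PromoterSet,
    top_genes: Iterable[str],
    consensus: str,
    background_rate: float,
) -> tuple[int, int, float]:
    """Exact upper binomial tail for consensus-site presence in top genes.

    Counts top-ranked genes whose promoter carries >= 1 bidirectional match of
    the (possibly degenerate) consensus and returns (k, n, P(X >= k)) for
    X ~ Binomial(n, background_rate).
    """
    if not 0.0 < background_rate < 1.0:
        raise ValueError("background_rate must lie in (0, 1)")
    top = list(top_genes)
    if not top:
        raise ValueError("empty top gene set")
    subset = PromoterSet(
        {g: promoters.sequences[g] for g in top}, half_width=promoters.half_width
    )
    hits = scan_presence(subset, consensus, bidirectional=True)
    k, n = len(hits), len(top)
    p_tail = float(stats.binom.sf(k - 1, n, background_rate))
    return k, n, p_tail


# ---------------------------------------------------------------------------
# exhaustive scan
# ---------------------------------------------------------------------------

def enrichment_scan(
    ranked: pd.DataFrame,
    promoters: PromoterSet,
    min_len: int = 6,
    max_len: int = 6,
    include_gapped9: bool = False,
    bidirectional: bool = True,
    exact_threshold: int = 8,
    n_motifs_tested: int | None = None,
) -> pd.DataFrame:
    """Exhaustive rank-based enrichment over all words in a length range.

    Returns one record per motif (canonical form in bidirectional mode):
    motif, n_with, n_total, U, p_raw, p_adj, delta_median, testable — sorted
    by ascending adjusted p, ties broken by |delta_median| descending, then
    motif string.
    """
    genes = set(ranked["gene_id"])
    missing = genes - set(promoters.sequences)
    if missing:
        raise ValueError(
            f"{len(missing)} ranked genes lack promoter sequences, "
            f"e.g. {sorted(missing)[:3]}"
        )
    motifs = enumerate_motifs(
        min_len, max_len, include_gapped9=include_gapped9,
        canonicalize=bidirectional,
    )
    presence: dict[str, set[str]] = {}
    for k in range(min_len, max_len + 1):
        presence.update(kmer_presence_index(promoters, k, bidirectional))
    if include_gapped9:
        presence.update(gapped9_presence_index(promoters, bidirectional))

    n_tested = n_motifs_tested if n_motifs_tested is not None else len(motifs)
    gene_rank = dict(zip(ranked["gene_id"], ranked["rank"].astype(float)))
    all_ranks = np.array([gene_rank[g] for g in gene_rank], dtype=float)
    n_total = len(gene_rank)

    rows = []
    for motif in motifs:
        with_genes = presence.get(motif, set()) & genes
        m = len(with_genes)
        if m == 0 or m == n_total:
            rows.append((motif, m, n_total, np.nan, 1.0, 1.0, np.nan, False))
            continue
        ranks_with = np.fromiter(
            (gene_rank[g] for g in with_genes), dtype=float, count=m
        )
        method = "exact" if min(m, n_total - m) <= exact_threshold else "asymptotic"
        mask = np.isin(all_ranks, ranks_with)
        res = stats.mannwhitneyu(
            ranks_with, all_ranks[~mask], alternative="two-sided", method=method
        )
        dmed = (float(np.median(ranks_with)) - (n_total + 1) / 2.0) / n_total
        p_adj = min(1.0, float(res.pvalue) * n_tested)
        rows.append(
            (motif, m, n_total, float(res.statistic), float(res.pvalue),
             p_adj, dmed, True)
        )
    out = pd.DataFrame(
        rows,
        columns=["motif", "n_with", "n_total", "U", "p_raw", "p_adj",
                 "delta_median", "testable"],
    )
    out["_absdm"] = out["delta_median"].abs().fillna(-1.0)
    out = out.sort_values(
        ["p_adj", "_absdm", "motif"], ascending=[True, False, True]
    ).drop(columns="_absdm").reset_index(drop=True)
    return out
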