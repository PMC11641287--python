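"""Seed-match sponge-site prediction on circular transcripts.

A circRNA sequesters a miRNA through miRNA response elements: stretches
complementary to the miRNA seed (nucleotides 2-7/2-8).  Site classes, in
increasing specificity: 6mer (Watson-Crick match to positions 2-7),
7mer-A1 (6mer plus an A opposite miRNA position 1), 7mer-m8 (match to
positions 2-8), and 8mer (7mer-m8 plus the A1 anchor).  Because the
transcript is covalently closed at the back-splice junction, scanning
treats the sequence as a ring by default: sites may span the junction and
positions are reported modulo the length, 0-based on the linearized circle
starting at the junction.

Each site gets a deterministic additive context score (type term plus a
local AU-content term; more negative = stronger) and a percentile rank of
that score among a background of predicted sites, mirroring how public
interactome resources report "context percentile".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RNA_ALPHABET

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_SPECIFICITY = {t: i for i, t in enumerate(SITE_TYPES)}  # lower = more specific
_SITE_LENGTH = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}

#: additive contribution of the match class to the context score
TYPE_SCORE = {"8mer": -0.31, "7mer-m8": -0.16, "7mer-A1": -0.10, "6mer": -0.02}
#: weight of the local AU-content term (AU-rich flanks favor accessibility)
AU_WEIGHT = -0.1
#: flank length considered on each side of the site
FLANK = 15

_COMPLEMENT = str.maketrans("AUCG", "UAGC")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_rna(seq: str, what: str) -> None:
    extra = set(seq) - RNA_ALPHABET
    if extra:
        raise ValueError(f"{what}: invalid RNA characters {sorted(extra)}")


@dataclass
class SpongeSite:
    """One predicted miRNA response element on a circRNA."""

    circ_id: str
    mirna_id: str
    site_type: str
    position: int  # 0-based 5' end of the site on the linearized circle
    score: float | None = None
    percentile: float | None = None


def find_seed_sites(
    circ_seq: str, mirna_seq: str, circular: bool = True,
    circ_id: str = "", mirna_id: str = "",
) -> list[SpongeSite]:
    """All seed-complementary sites of a miRNA on a circRNA.

    The target site, read 5'->3' on the circRNA, is the reverse complement
    of the miRNA seed; miRNA position 1 lies opposite the target nucleotide
    immediately 3' of the seed match, and the A1 classes require an A
    there.  With ``circular=True`` the sequence is scanned as a ring, so
    sites may span the back-splice junction.  Each seed-match locus is
    reported once with its most specific type.
    """
    circ_seq = circ_seq.upper()
    mirna_seq = mirna_seq.upper()
    _check_rna(circ_seq, "circRNA sequence")
    _check_rna(mirna_seq, "miRNA sequence")
    if len(mirna_seq) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    L = len(circ_seq)
    core = _revcomp(mirna_seq[1:7])  # complement of seed positions 2-7
    m8c = _revcomp(mirna_seq[7])     # complement of position 8
    if L < 6:
        return []

    if circular:
        doubled = circ_seq + circ_seq
        scan_range = range(L)

        def at(i: int) -> str:
            return circ_seq[i % L]
    else:
        doubled = circ_seq
        scan_range = range(L - 5)

        def at(i: int) -> str:
            return circ_seq[i] if 0 <= i < L else ""

    sites: list[SpongeSite] = []
    for q in scan_range:
        if doubled[q : q + 6] != core:
            continue
        has_m8 = at(q - 1) == m8c if (circular or q - 1 >= 0) else False
        has_a1 = at(q + 6) == "A" if (circular or q + 6 < L) else False
        if has_m8 and has_a1:
            site_type = "8mer"
        elif has_m8:
            site_type = "7mer-m8"
        elif has_a1:
            site_type = "7mer-A1"
        else:
            site_type = "6mer"
        start = (q - 1) % L if site_type in ("8mer", "7mer-m8") else q % L
        sites.append(
            SpongeSite(circ_id=circ_id, mirna_id=mirna_id,
                       site_type=site_type, position=start)
        )
    return sites


def context_score(site: SpongeSite, circ_seq: str, circular: bool = True) -> SpongeSite:
    """Attach the additive context score: type term + AU-flank term.

    The AU term is ``AU_WEIGHT`` times the A/U fraction of the 30 nt
    flanking the site (15 each side, wrapping across the junction on the
    ring).  More negative scores mean stronger predicted binding.
    """
    circ_seq = circ_seq.upper()
    L = len(circ_seq)
    length = _SITE_LENGTH[site.site_type]
    start, end = site.position, site.position + length
    flank_chars: list[str] = []
    if circular:
        for i in range(start - FLANK, start):
            flank_chars.append(circ_seq[i % L])
        for i in range(end, end + FLANK):
            flank_chars.append(circ_seq[i % L])
    else:
        flank_chars.extend(circ_seq[max(0, start - FLANK) : start])
        flank_chars.extend(circ_seq[end : min(L, end + FLANK)])
    if flank_chars:
        au = sum(c in "AU" for c in flank_chars) / len(flank_chars)
    else:
        au = 0.0
    site.score = TYPE_SCORE[site.site_type] + AU_WEIGHT * au
    return site


def context_percentile(sites: list[SpongeSite]) -> list[SpongeSite]:
    """Percentile-rank scored sites: 100 = strongest (most negative) score.

    percentile = 100 * (#sites with strictly weaker score) / (total - 1);
    a single site gets 100; ties share a percentile.
    """
    if not sites:
        raise ValueError("context_percentile needs at least one scored site")
    scores = np.array([s.score for s in sites], dtype=float)
    if np.any(np.isnan(scores)):
        raise ValueError("all sites must be scored first")
    n = len(sites)
    if n == 1:
        sites[0].percentile = 100.0
        return sites
    for site in sites:
        weaker = int(np.sum(scores > site.score))  # larger = weaker binding
        site.percentile = 100.0 * weaker / (n - 1)
    return sites


def sites_to_frame(sites: list[SpongeSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "circ_id": s.circ_id,
                "mirna_id": s.mirna_id,
                "site_type": s.site_type,
                "position": s.position,
                "score": s.score,
                "context_percentile": s.percentile,
            }
            for s in sites
        ],
        columns=["circ_id", "mirna_id", "site_type", "position", "score",
                 "context_percentile"],
    )


def scan_pairs(
    circ_seqs: dict[str, str], mirna_seqs: dict[str, str], circular: bool = True
) -> pd.DataFrame:
    """Scan every circRNA against every miRNA, score, and percentile-rank.

    Percentiles are computed over the pooled background of all predicted
    sites in the scan.  Returns one row per site.
    """
    all_sites: list[SpongeSite] = []
    for circ_id, cseq in circ_seqs.items():
        for mirna_id, mseq in mirna_seqs.items():
            found = find_seed_sites(cseq, mseq, circular=circular,
                                    circ_id=circ_id, mirna_id=mirna_id)
            for site in found:
                context_score(site, cseq, circular=circular)
            all_sites.extend(found)
    if all_sites:
        context_percentile(all_sites)
    return sites_to_frame(all_sites)


def filter_high_confidence(
    sites: pd.DataFrame, circ_de: pd.DataFrame, min_percentile: float = 72.0
) -> pd.DataFrame:
    """Reduce sites to unique high-confidence (circ, miRNA) candidate pairs.

    A pair is kept when its best site reaches ``min_percentile``
    (inclusive) and the circRNA is significantly differentially expressed.
    The retained row carries the pair's best site type and percentile.
    """
    cols = ["circ_id", "mirna_id", "site_type", "context_percentile"]
    if sites.empty:
        return pd.DataFrame(columns=cols)
    sig_circ = set(circ_de.index[circ_de["direction"] != "ns"])
    kept = sites[sites["circ_id"].isin(sig_circ)]
    if kept.empty:
        return pd.DataFrame(columns=cols)
    best = (
        kept.sort_values(
            ["context_percentile", "site_type"],
            ascending=[False, True],
            key=lambda s: s.map(_SPECIFICITY) if s.name == "site_type" else s,
        )
        .groupby(["circ_id", "mirna_id"], as_index=False, sort=True)
        .first()
    )
    best = best[best["context_percentile"] >= min_percentile]
    return best[cols].reset_index(drop=True)
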