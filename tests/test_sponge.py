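"""Seed-site scanning, context scoring, percentile ranking and pair filtering."""

import numpy as np
import pandas as pd
import pytest

from circaxis import (
    SpongeSite,
    context_percentile,
    context_score,
    filter_high_confidence,
    find_seed_sites,
)
from circaxis.sponge import _revcomp, SITE_TYPES, _SITE_LENGTH, TYPE_SCORE

MIRNA = "UAGCUUAUCAGACUGAUGUUGA"  # 22 nt

CORE6 = _revcomp(MIRNA[1:7])
SITE8 = _revcomp(MIRNA[1:8]) + "A"


def brute_force_scan(circ_seq: str, mirna_seq: str, circular: bool):
    """Independent oracle: test every rotation window on the doubled sequence."""
    L = len(circ_seq)
    doubled = circ_seq + circ_seq
    core = _revcomp(mirna_seq[1:7])
    m8c = _revcomp(mirna_seq[7])
    found = {}
    positions = range(L) if circular else range(L - 5)
    for q in positions:
        window = doubled[q:q + 6] if circular else circ_seq[q:q + 6]
        if window != core:
            continue
        if circular:
            prev_c, next_c = doubled[(q - 1) % L], doubled[(q + 6) % L]
        else:
            prev_c = circ_seq[q - 1] if q >= 1 else ""
            next_c = circ_seq[q + 6] if q + 6 < L else ""
        m8, a1 = prev_c == m8c, next_c == "A"
        t = "8mer" if m8 and a1 else "7mer-m8" if m8 else "7mer-A1" if a1 else "6mer"
        start = (q - 1) % L if t in ("8mer", "7mer-m8") else q % L
        found[q % L] = (t, start)
    return found


def _random_rna(rng, n):
    return "".join(rng.choice(list("AUCG"), size=n))


def _plant(seq: str, insert: str, offset: int) -> str:
    chars = list(seq)
    for i, c in enumerate(insert):
        chars[(offset + i) % len(seq)] = c
    return "".join(chars)


class TestFindSeedSites:
    def test_no_complement_gives_empty(self):
        # all-G circle cannot pair with this seed
        assert find_seed_sites("G" * 100, MIRNA) == []

    def test_planted_8mer_found_at_offset(self, rng):
        for _ in range(20):  # background rejection-sampled to one site
            bg = _random_rna(rng, 300)
            if len(brute_force_scan(_plant(bg, SITE8, 50), MIRNA, True)) == 1:
                break
        seq = _plant(bg, SITE8, 50)
        sites = find_seed_sites(seq, MIRNA)
        assert len(sites) == 1
        assert sites[0].site_type == "8mer"
        assert sites[0].position == 50

    def test_junction_spanning_site_needs_circular(self, rng):
        for _ in range(50):
            bg = _random_rna(rng, 300)
            seq = _plant(bg, SITE8, 296)  # last 4 nt + first 4 nt of the ring
            if len(brute_force_scan(seq, MIRNA, True)) == 1:
                break
        circular = find_seed_sites(seq, MIRNA, circular=True)
        linear = find_seed_sites(seq, MIRNA, circular=False)
        assert [s.position for s in circular] == [296]
        assert linear == []

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError, match="invalid RNA"):
            find_seed_sites("ACGT", MIRNA)
        with pytest.raises(ValueError, match="at least 8"):
            find_seed_sites("AUCG" * 10, "AUCGAUC")

    @pytest.mark.parametrize("circular", [True, False])
    def test_matches_brute_force_on_random_pairs(self, rng, circular):
        """200 random (circRNA, miRNA) pairs against the doubled-sequence oracle."""
        for _ in range(200):
            L = int(rng.integers(30, 120))
            circ = _random_rna(rng, L)
            mirna = _random_rna(rng, int(rng.integers(18, 24)))
            # bias toward hits: sometimes plant a site
            if rng.random() < 0.5:
                circ = _plant(circ, _revcomp(mirna[1:8]) + "A",
                              int(rng.integers(0, L)))
            got = {
                s.position: s.site_type
                for s in find_seed_sites(circ, mirna, circular=circular)
            }
            expected = {start: t for t, start in
                        brute_force_scan(circ, mirna, circular).values()}
            assert got == expected

    def test_site_count_bounded_by_length(self):
        # a ring of repeated cores: every offset matches, but each locus
        # is reported exactly once
        seq = (CORE6 * 20)[:60]
        sites = find_seed_sites(seq, MIRNA)
        assert len(sites) <= 60
        assert len({s.position for s in sites}) == len(sites)


class TestContextScore:
    def test_8mer_in_gc_flank(self):
        seq = _plant("G" * 100, SITE8, 40)
        [site] = find_seed_sites(seq, MIRNA)
        context_score(site, seq)
        # flank is all G except any A/U inside... position 40 flank is pure G
        assert site.score == pytest.approx(-0.31)

    def test_6mer_in_au_flank(self):
        mirna = "UGGGGGGGCCCCCCCCCCCCCC"  # seed GGGGGG -> core CCCCCC
        core = _revcomp(mirna[1:7])
        seq = _plant("U" * 100, core, 40)
        sites = find_seed_sites(seq, mirna)
        [site] = [s for s in sites if s.site_type == "6mer" and s.position == 40]
        context_score(site, seq)
        assert site.score == pytest.approx(-0.02 - 0.1)

    def test_type_ordering_at_fixed_flank(self):
        # stronger classes never score weaker at identical AU context
        assert (TYPE_SCORE["8mer"] < TYPE_SCORE["7mer-m8"]
                < TYPE_SCORE["7mer-A1"] < TYPE_SCORE["6mer"])

    def test_hand_summed_planted_site(self, rng):
        seq = _plant(_random_rna(rng, 200), SITE8, 100)
        sites = [s for s in find_seed_sites(seq, MIRNA) if s.position == 100]
        [site] = sites
        context_score(site, seq)
        flank = seq[85:100] + seq[108:123]
        expected = -0.31 - 0.1 * sum(c in "AU" for c in flank) / 30
        assert site.score == pytest.approx(expected)


def _scored(scores):
    sites = [SpongeSite("c", "m", "6mer", i, score=s) for i, s in enumerate(scores)]
    return context_percentile(sites)


class TestContextPercentile:
    def test_single_site_gets_100(self):
        assert _scored([-0.2])[0].percentile == 100.0

    def test_rank_arithmetic(self):
        sites = _scored([-0.4, -0.3, -0.2, -0.1])
        assert [s.percentile for s in sites] == pytest.approx(
            [100.0, 200 / 3, 100 / 3, 0.0])

    def test_all_ties_share_zero(self):
        assert all(s.percentile == 0.0 for s in _scored([-0.2, -0.2, -0.2]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            context_percentile([])

    def test_invariance_under_order_and_monotone_transform(self, rng):
        scores = list(rng.normal(-0.2, 0.1, size=50))
        base = {s.position: s.percentile for s in _scored(scores)}
        perm = rng.permutation(50)
        shuffled = [SpongeSite("c", "m", "6mer", int(i), score=scores[i])
                    for i in perm]
        for s in context_percentile(shuffled):
            assert s.percentile == pytest.approx(base[s.position])
        # strictly increasing transform preserves the ranking
        transformed = _scored([np.tanh(3 * x) + 0.1 * x for x in scores])
        for s in transformed:
            assert s.percentile == pytest.approx(base[s.position])


class TestFilterHighConfidence:
    def _circ_de(self, ids, direction="down"):
        return pd.DataFrame({"direction": [direction] * len(ids)},
                            index=pd.Index(ids, name="feature_id"))

    def test_boundary_percentile_is_inclusive(self):
        sites = pd.DataFrame({
            "circ_id": ["c1", "c2", "c3", "c4", "c5"],
            "mirna_id": ["m1", "m1", "m2", "m2", "m3"],
            "site_type": ["8mer"] * 5,
            "position": [0] * 5,
            "score": [-0.4] * 5,
            "context_percentile": [99.0, 86.0, 72.0, 73.0, 87.0],
        })
        de = self._circ_de(["c1", "c2", "c3", "c4", "c5"])
        kept = filter_high_confidence(sites, de, min_percentile=72)
        assert len(kept) == 5  # 72 retained: the threshold is >=

    def test_below_threshold_excluded(self):
        sites = pd.DataFrame({
            "circ_id": ["c1"], "mirna_id": ["m1"], "site_type": ["6mer"],
            "position": [0], "score": [-0.1], "context_percentile": [50.0]})
        kept = filter_high_confidence(sites, self._circ_de(["c1"]), 72)
        assert kept.empty

    def test_nonsignificant_circ_excluded(self):
        sites = pd.DataFrame({
            "circ_id": ["c1"], "mirna_id": ["m1"], "site_type": ["8mer"],
            "position": [0], "score": [-0.4], "context_percentile": [99.0]})
        kept = filter_high_confidence(sites, self._circ_de(["c1"], "ns"), 72)
        assert kept.empty

    def test_empty_sites(self):
        kept = filter_high_confidence(pd.DataFrame(), self._circ_de(["c1"]), 72)
        assert kept.empty

    def test_pair_keeps_best_site(self):
        sites = pd.DataFrame({
            "circ_id": ["c1", "c1"], "mirna_id": ["m1", "m1"],
            "site_type": ["6mer", "8mer"], "position": [5, 50],
            "score": [-0.05, -0.35], "context_percentile": [10.0, 95.0]})
        kept = filter_high_confidence(sites, self._circ_de(["c1"]), 72)
        assert len(kept) == 1
        assert kept.loc[0, "site_type"] == "8mer"
        assert kept.loc[0, "context_percentile"] == 95.0
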