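"""Fragment maps, region classification and residue histograms."""

import numpy as np
import pytest

from adductms.fragments import (
    enumerate_oligo_internal,
    enumerate_oligo_terminal,
    enumerate_peptide,
    precursor,
)
from adductms.ions import BUILTIN_ADDUCTS, build_species
from adductms.matching import MatchResult
from adductms.reporting import (
    build_fragment_map,
    classify_regions,
    histogram_to_tsv,
    map_to_svg,
    residue_histogram,
)

PT_NH3_2 = BUILTIN_ADDUCTS["Pt(NH3)2"]


def _match(fragment, adducts=None, protons_removed=1, similarity=0.95):
    species = build_species(fragment, adducts or {}, 0, protons_removed)
    return MatchResult(
        species=species,
        similarity=similarity,
        observed_mz=species.mz,
        ppm_error=0.0,
        matched_pairs=((0, 0),),
    )


@pytest.fixture()
def oligo_matches(s1):
    terminal = {f.label: f for f in enumerate_oligo_terminal(s1, "aw")}
    internal = {f.label: f for f in enumerate_oligo_internal(s1, ["w"], ["a"])}
    return terminal, internal


class TestFragmentMap:
    def test_empty_match_list(self, s1):
        fmap = build_fragment_map([], s1)
        assert fmap.tracks == ()
        assert fmap.platinated_counts.sum() == 0
        assert fmap.unplatinated_counts.sum() == 0

    def test_single_platinated_track_tally(self, s1, oligo_matches):
        terminal, _ = oligo_matches
        result = _match(terminal["a9"], {PT_NH3_2: 1}, protons_removed=4)
        fmap = build_fragment_map([result], s1)
        assert list(fmap.platinated_counts) == [1] * 9 + [0] * 4
        assert fmap.unplatinated_counts.sum() == 0

    def test_charge_states_collapse_to_one_track(self, s1, oligo_matches):
        terminal, _ = oligo_matches
        frag = terminal["a9"]
        results = [
            _match(frag, {PT_NH3_2: 1}, protons_removed=k, similarity=s)
            for k, s in ((3, 0.8), (4, 1.0))
        ]
        fmap = build_fragment_map(results, s1)
        assert len(fmap.tracks) == 1
        assert fmap.tracks[0].mean_similarity == pytest.approx(0.9)
        assert fmap.tracks[0].n_matches == 2
        assert fmap.platinated_counts.max() == 1

    def test_per_position_counts_match_brute_force(self, s1, oligo_matches):
        terminal, internal = oligo_matches
        rng = np.random.default_rng(11)
        pool = list(terminal.values()) + list(internal.values())
        chosen = rng.choice(len(pool), size=15, replace=False)
        results = [
            _match(pool[i], {PT_NH3_2: 1} if i % 2 else {}, protons_removed=3)
            for i in chosen
        ]
        fmap = build_fragment_map(results, s1)
        # independent recount over unique (label, platinated) fragments
        plat = np.zeros(len(s1), dtype=int)
        unplat = np.zeros(len(s1), dtype=int)
        seen = set()
        for r in results:
            key = (r.species.fragment.label, r.species.is_platinated)
            if key in seen:
                continue
            seen.add(key)
            arr = plat if r.species.is_platinated else unplat
            for pos in range(r.species.fragment.start, r.species.fragment.end + 1):
                arr[pos - 1] += 1
        assert list(fmap.platinated_counts) == list(plat)
        assert list(fmap.unplatinated_counts) == list(unplat)

    def test_mixed_sequences_rejected(self, s1, s1c):
        frag = enumerate_oligo_terminal(s1, ["a"])[0]
        with pytest.raises(ValueError, match="references"):
            build_fragment_map([_match(frag)], s1c)

    def test_svg_render(self, s1, oligo_matches):
        terminal, _ = oligo_matches
        results = [
            _match(terminal["a9"], {PT_NH3_2: 1}, 4, similarity=0.95),
            _match(terminal["w4"], similarity=0.8),
        ]
        svg = map_to_svg(build_fragment_map(results, s1))
        assert svg.startswith("<svg")
        assert "GTATTGGCACGTA"[0] in svg
        assert svg.count("<rect") == 2
        # sub-cutoff track drawn faded
        assert 'fill-opacity="0.35"' in svg


class TestClassifyRegions:
    def test_half_and_half(self, s1, oligo_matches):
        terminal, _ = oligo_matches
        results = [
            _match(terminal["a3"], {PT_NH3_2: 1}, protons_removed=3),
            _match(terminal["w4"], {PT_NH3_2: 1}, protons_removed=3),
        ]
        summary = {r.region: r for r in classify_regions(results)}
        assert summary["5'-end"].platinated_pct == pytest.approx(50.0)
        assert summary["3'-end"].platinated_pct == pytest.approx(50.0)
        assert summary["Middle"].platinated_pct == pytest.approx(0.0)

    def test_empty_evidence_set_flagged(self, s1, oligo_matches):
        terminal, _ = oligo_matches
        results = [_match(terminal["a3"])]  # unplatinated only
        for region in classify_regions(results):
            assert region.platinated_pct == 0.0
            assert region.platinated_empty
            assert not region.unplatinated_empty

    def test_percentages_sum_to_100_per_evidence_set(self, s1, oligo_matches):
        terminal, internal = oligo_matches
        rng = np.random.default_rng(5)
        pool = list(terminal.values()) + list(internal.values())
        results = [
            _match(pool[i], {PT_NH3_2: 1} if i % 3 == 0 else {}, protons_removed=3)
            for i in rng.choice(len(pool), size=20, replace=False)
        ]
        regions = classify_regions(results)
        assert sum(r.platinated_pct for r in regions) == pytest.approx(100.0, abs=0.01)
        assert sum(r.unplatinated_pct for r in regions) == pytest.approx(100.0, abs=0.01)
        # class counts sum to the per-set totals
        n_unique = len(
            {(r.species.fragment.label, r.species.is_platinated) for r in results}
        )
        assert sum(r.platinated_count + r.unplatinated_count for r in regions) == n_unique

    def test_count_all_counts_every_ion(self, s1, oligo_matches):
        terminal, _ = oligo_matches
        frag = terminal["a3"]
        results = [_match(frag, protons_removed=k) for k in (1, 2)]
        unique = classify_regions(results)
        every = classify_regions(results, count_all=True)
        assert sum(r.unplatinated_count for r in unique) == 1
        assert sum(r.unplatinated_count for r in every) == 2

    def test_brute_force_recount(self, s1, oligo_matches):
        terminal, internal = oligo_matches
        rng = np.random.default_rng(23)
        pool = list(terminal.values()) + list(internal.values())
        results = [
            _match(pool[i], {PT_NH3_2: 1} if i % 2 else {}, protons_removed=3)
            for i in rng.choice(len(pool), size=12, replace=False)
        ]
        regions = {r.region: r for r in classify_regions(results, count_all=True)}
        brute = {"terminal5": 0, "terminal3": 0, "internal": 0}
        for r in results:
            brute[r.species.fragment.kind] += 1
        assert regions["5'-end"].platinated_count + regions["5'-end"].unplatinated_count == brute["terminal5"]
        assert regions["3'-end"].platinated_count + regions["3'-end"].unplatinated_count == brute["terminal3"]
        assert regions["Middle"].platinated_count + regions["Middle"].unplatinated_count == brute["internal"]


class TestResidueHistogram:
    def test_single_y4_covers_c_terminal_four(self, p1):
        frags = {f.label: f for f in enumerate_peptide(p1, ["y"])}
        plat, unplat = residue_histogram([_match(frags["y4"])], p1)
        assert list(unplat) == [0] * 7 + [1] * 4
        assert plat.sum() == 0

    def test_complementary_pair_covers_each_position_once(self, p1):
        frags = {f.label: f for f in enumerate_peptide(p1, ["b", "y"])}
        results = [_match(frags["b4"]), _match(frags["y7"])]
        plat, unplat = residue_histogram(results, p1)
        assert list(unplat) == [1] * len(p1)

    def test_total_equals_sum_of_interval_lengths(self, s1, oligo_matches):
        terminal, internal = oligo_matches
        rng = np.random.default_rng(7)
        pool = list(terminal.values()) + list(internal.values())
        results = [
            _match(pool[i], {PT_NH3_2: 1} if i % 2 else {}, protons_removed=3)
            for i in rng.choice(len(pool), size=10, replace=False)
        ]
        plat, unplat = residue_histogram(results, s1)
        expected = sum(r.species.fragment.length for r in results)
        assert plat.sum() + unplat.sum() == expected

    def test_precursors_excluded(self, s1):
        results = [_match(precursor(s1), {PT_NH3_2: 1}, protons_removed=8)]
        plat, unplat = residue_histogram(results, s1)
        assert plat.sum() == 0 and unplat.sum() == 0

    def test_tsv_export(self, p1):
        frags = {f.label: f for f in enumerate_peptide(p1, ["y"])}
        plat, unplat = residue_histogram([_match(frags["y4"])], p1)
        text = histogram_to_tsv(p1, plat, unplat)
        assert text.splitlines()[0] == "position\tresidue\tplatinated\tunplatinated"
        assert "11\tE\t0\t1" in text
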