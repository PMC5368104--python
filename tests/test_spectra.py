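"""Peak-list I/O, ppm cosine similarity, library search and the dataset split."""

import itertools

import numpy as np
import pytest

from molcontest import (
    Spectrum,
    cosine_similarity,
    dedupe_spectra,
    library_search,
    quality_filter,
    read_mgf,
    read_peaklist,
    split_train_challenge,
    write_mgf,
    write_peaklist,
)


def spec(mz, intensity, **kwargs):
    return Spectrum(np.asarray(mz, float), np.asarray(intensity, float), **kwargs)


def separated_random_spectrum(rng, n_peaks, spacing_da=1.0):
    """Random spectrum whose peaks are far apart relative to ppm tolerances."""
    mz = np.sort(rng.uniform(100, 900, size=n_peaks))
    while np.any(np.diff(mz) < spacing_da):
        mz = np.sort(rng.uniform(100, 900, size=n_peaks))
    return spec(mz, rng.uniform(1, 100, size=n_peaks))


def optimal_assignment_cosine(a, b, tol_ppm):
    """Exhaustive optimal one-to-one matching oracle (sqrt intensities)."""
    ia, ib = np.sqrt(a.intensity), np.sqrt(b.intensity)
    allowed = np.abs(a.mz[:, None] - b.mz[None, :]) <= (
        np.maximum(a.mz[:, None], b.mz[None, :]) * tol_ppm * 1e-6
    )
    n, m = len(ia), len(ib)
    best = 0.0
    # enumerate every full injection of the smaller side into the larger;
    # disallowed pairs contribute 0, so partial matchings are dominated
    if n <= m:
        for subset in itertools.permutations(range(m), n):
            total = sum(ia[i] * ib[j] for i, j in enumerate(subset) if allowed[i, j])
            best = max(best, total)
    else:
        for subset in itertools.permutations(range(n), m):
            total = sum(ia[i] * ib[j] for j, i in enumerate(subset) if allowed[i, j])
            best = max(best, total)
    return best / (np.linalg.norm(ia) * np.linalg.norm(ib))


class TestSpectrumModel:
    def test_unsorted_input_is_sorted_with_notice(self, caplog):
        with caplog.at_level("INFO", logger="molcontest"):
            s = spec([300.0, 100.0, 200.0], [1.0, 2.0, 3.0])
        assert list(s.mz) == [100.0, 200.0, 300.0]
        assert list(s.intensity) == [2.0, 3.0, 1.0]
        assert "unsorted" in caplog.text

    def test_invalid_spectra_rejected(self):
        with pytest.raises(ValueError):
            spec([], [])
        with pytest.raises(ValueError):
            spec([100.0], [0.0])  # all-zero intensity
        with pytest.raises(ValueError):
            spec([-5.0], [1.0])


class TestPeaklistIO:
    def test_plain_text_round_trip(self, tmp_path, rng):
        original = separated_random_spectrum(rng, 8)
        path = tmp_path / "peaks.txt"
        write_peaklist(original, path)
        back = read_peaklist(path)
        np.testing.assert_array_equal(back.mz, original.mz)
        np.testing.assert_array_equal(back.intensity, original.intensity)

    def test_plain_text_parses_three_lines(self, tmp_path):
        path = tmp_path / "peaks.txt"
        path.write_text("# comment\n100.05 1200\n200.1 800\n300.2 50\n")
        s = read_peaklist(path)
        assert s.n_peaks == 3

    def test_mgf_round_trip_with_precursor_and_mode(self, tmp_path, rng):
        originals = [
            Spectrum(np.array([100.0, 200.0]), np.array([5.0, 1.0]),
                     precursor_mz=301.1234, ion_mode="positive", spectrum_id="s1"),
            Spectrum(np.array([150.0, 250.0, 350.0]), np.array([1.0, 2.0, 3.0]),
                     precursor_mz=401.5, ion_mode="negative", spectrum_id="s2"),
        ]
        path = tmp_path / "set.mgf"
        write_mgf(originals, path)
        back = read_mgf(path)
        assert [s.spectrum_id for s in back] == ["s1", "s2"]
        for orig, rec in zip(originals, back):
            np.testing.assert_allclose(rec.mz, orig.mz)
            np.testing.assert_allclose(rec.intensity, orig.intensity)
            assert rec.precursor_mz == pytest.approx(orig.precursor_mz)
            assert rec.ion_mode == orig.ion_mode

    def test_single_block_mgf_readable_as_peaklist(self, tmp_path):
        path = tmp_path / "one.mgf"
        write_mgf([spec([100.0], [1.0], precursor_mz=200.0, spectrum_id="q")], path)
        s = read_peaklist(path, fmt="mgf")
        assert s.precursor_mz == pytest.approx(200.0)


class TestCosine:
    def test_self_similarity_is_one(self, rng):
        for n in (1, 3, 10):
            s = separated_random_spectrum(rng, n)
            assert cosine_similarity(s, s, 10.0) == pytest.approx(1.0)

    def test_tolerance_disjoint_spectra_score_zero(self):
        a = spec([100.0, 200.0], [1.0, 1.0])
        b = spec([150.0, 250.0], [1.0, 1.0])
        assert cosine_similarity(a, b, 10.0) == 0.0

    def test_symmetric(self, rng):
        a = separated_random_spectrum(rng, 6)
        b = separated_random_spectrum(rng, 5)
        assert cosine_similarity(a, b, 20.0) == pytest.approx(
            cosine_similarity(b, a, 20.0))

    def test_invariant_to_uniform_intensity_scaling(self, rng):
        a = separated_random_spectrum(rng, 6)
        b = separated_random_spectrum(rng, 6)
        scaled = spec(b.mz, b.intensity * 37.5)
        assert cosine_similarity(a, scaled, 20.0) == pytest.approx(
            cosine_similarity(a, b, 20.0))

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(10):
            a = separated_random_spectrum(rng, 5)
            b = separated_random_spectrum(rng, 7)
            value = cosine_similarity(a, b, 50.0)
            assert 0.0 <= value <= 1.0

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_exhaustive_assignment_oracle_on_small_spectra(self, trial):
        rng = np.random.default_rng(5000 + trial)
        a = separated_random_spectrum(rng, int(rng.integers(2, 7)))
        # b: jittered copy of a subset of a's peaks plus unrelated peaks
        take = rng.random(a.n_peaks) < 0.7
        mz = np.concatenate([a.mz[take] * (1 + rng.normal(0, 3e-6, take.sum())),
                             rng.uniform(950, 1000, size=2)])
        inten = rng.uniform(1, 100, size=len(mz))
        b = spec(np.sort(mz), inten[np.argsort(mz)])
        ours = cosine_similarity(a, b, 10.0)
        oracle = optimal_assignment_cosine(a, b, 10.0)
        assert ours == pytest.approx(oracle, abs=1e-9)

    def test_raw_scaling_mode(self):
        a = spec([100.0, 200.0], [4.0, 1.0])
        b = spec([100.0, 200.0], [4.0, 1.0])
        assert cosine_similarity(a, b, 10.0, scaling="raw") == pytest.approx(1.0)


class TestLibrarySearch:
    def _library(self):
        return [
            spec([100.0, 200.0], [1.0, 2.0], precursor_mz=300.0,
                 spectrum_id="ref1", structure_key="AAAAAAAAAAAAAA"),
            spec([100.0, 210.0], [2.0, 1.0], precursor_mz=300.001,
                 spectrum_id="ref2", structure_key="BBBBBBBBBBBBBB"),
            spec([100.0, 200.0], [1.0, 2.0], precursor_mz=500.0,
                 spectrum_id="ref3", structure_key="CCCCCCCCCCCCCC"),
        ]

    def test_no_precursor_in_window_returns_empty(self):
        query = spec([100.0], [1.0], precursor_mz=400.0)
        assert library_search(query, self._library()) == []

    def test_single_survivor_returned_regardless_of_similarity(self):
        # no fragment matches at all, but the lone precursor match is a hit
        query = spec([999.0], [1.0], precursor_mz=500.0)
        hits = library_search(query, self._library())
        assert len(hits) == 1
        assert hits[0].spectrum_id == "ref3"
        assert hits[0].similarity == 0.0

    def test_planted_true_spectrum_retrieved_rank_one(self, rng):
        library = []
        for i in range(30):
            s = separated_random_spectrum(rng, 10)
            library.append(Spectrum(s.mz, s.intensity, precursor_mz=300.0,
                                    spectrum_id=f"ref{i}",
                                    structure_key=f"K{i:013d}".replace("0", "Q")))
        true = library[7]
        q_mz = true.mz * (1 + rng.normal(0, 2e-6, true.n_peaks))
        q_int = true.intensity * np.exp(rng.normal(0, 0.05, true.n_peaks))
        query = Spectrum(np.sort(q_mz), q_int[np.argsort(q_mz)], precursor_mz=300.0)
        hits = library_search(query, library)
        assert hits[0].spectrum_id == "ref7"
        assert len(hits) == 30

    def test_ion_mode_mismatch_excluded(self):
        library = [spec([100.0], [1.0], precursor_mz=300.0,
                        ion_mode="negative", spectrum_id="neg")]
        query = spec([100.0], [1.0], precursor_mz=300.0, ion_mode="positive")
        assert library_search(query, library) == []


class TestSplit:
    def _fixed_similarity(self, table):
        return lambda query, ref: table[query.spectrum_id]

    def _spectra(self, sims):
        return [spec([100.0], [1.0], spectrum_id=sid) for sid in sims]

    def test_above_threshold_goes_to_training(self):
        sims = {"s086": 0.86, "s050": 0.50}
        library = [spec([100.0], [1.0], spectrum_id="lib")]
        training, challenge = split_train_challenge(
            self._spectra(sims), library, similarity=self._fixed_similarity(sims))
        assert [s.spectrum_id for s in training] == ["s086"]
        assert [s.spectrum_id for s in challenge] == ["s050"]

    def test_exactly_at_threshold_is_challenge(self):
        sims = {"s085": 0.85}
        library = [spec([100.0], [1.0], spectrum_id="lib")]
        training, challenge = split_train_challenge(
            self._spectra(sims), library, similarity=self._fixed_similarity(sims))
        assert training == []
        assert [s.spectrum_id for s in challenge] == ["s085"]

    def test_exception_forced_to_challenge_despite_high_similarity(self):
        sims = {"alizarin": 0.88, "other": 0.88}
        library = [spec([100.0], [1.0], spectrum_id="lib")]
        training, challenge = split_train_challenge(
            self._spectra(sims), library, exceptions=["alizarin"],
            similarity=self._fixed_similarity(sims))
        assert [s.spectrum_id for s in training] == ["other"]
        assert [s.spectrum_id for s in challenge] == ["alizarin"]

    def test_partition_total_disjoint_and_threshold_monotone(self, rng):
        sims = {f"s{i}": float(rng.uniform()) for i in range(50)}
        spectra_list = self._spectra(sims)
        library = [spec([100.0], [1.0], spectrum_id="lib")]
        previous_training = None
        for threshold in (0.2, 0.5, 0.8, 0.95):
            training, challenge = split_train_challenge(
                spectra_list, library, threshold=threshold,
                similarity=self._fixed_similarity(sims))
            ids = {s.spectrum_id for s in training} | {s.spectrum_id for s in challenge}
            assert ids == set(sims)
            assert len(training) + len(challenge) == len(sims)
            if previous_training is not None:
                # raising the threshold never moves challenge -> training
                assert {s.spectrum_id for s in training} <= previous_training
            previous_training = {s.spectrum_id for s in training}


class TestDedupeAndQuality:
    def test_byte_identical_peak_lists_kept_once(self):
        a = spec([100.0, 200.0], [1.0, 2.0], spectrum_id="a")
        b = spec([100.0, 200.0], [1.0, 2.0], spectrum_id="b")
        c = spec([100.0, 200.0], [1.0, 2.5], spectrum_id="c")
        out = dedupe_spectra([a, b, c])
        assert [s.spectrum_id for s in out] == ["a", "c"]

    def test_same_substance_collapses_to_highest_max_intensity(self):
        first = spec([100.0], [1e6], spectrum_id="m1", ion_mode="positive")
        second = spec([100.0, 110.0], [5e5, 1e5], spectrum_id="m2", ion_mode="positive")
        out = dedupe_spectra([first, second],
                             substance_of={"m1": "caffeine", "m2": "caffeine"})
        assert [s.spectrum_id for s in out] == ["m1"]

    def test_same_substance_different_modes_both_kept(self):
        pos = spec([100.0], [1e6], spectrum_id="p", ion_mode="positive")
        neg = spec([100.0, 110.0], [1e6, 1.0], spectrum_id="n", ion_mode="negative")
        out = dedupe_spectra([pos, neg], substance_of={"p": "x", "n": "x"})
        assert len(out) == 2

    def test_no_duplicates_is_identity(self, rng):
        spectra_list = [separated_random_spectrum(rng, 4) for _ in range(5)]
        assert dedupe_spectra(spectra_list) == spectra_list

    def test_quality_filter_drops_single_peak_and_weak_spectra(self):
        good = spec([100.0, 200.0], [2e5, 1e5], spectrum_id="good")
        single = spec([100.0], [1e6], spectrum_id="single")
        weak = spec([100.0, 200.0], [5e4, 2e4], spectrum_id="weak")
        kept = quality_filter([good, single, weak])
        assert [s.spectrum_id for s in kept] == ["good"]
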