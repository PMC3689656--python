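"""Feature catalog structure and window encoding semantics."""

import numpy as np
import pytest

from pyruvoylsite.constants import ATCHLEY_FACTORS
from pyruvoylsite.features import (
    build_catalog,
    encode_all,
    encode_window,
    fit_frequency_table,
)
from pyruvoylsite.windowing import PeptideWindow, WindowConfig, build_sample_set


class TestCatalog:
    @pytest.mark.parametrize(
        "w,total", [(7, 474), (8, 538), (9, 602), (10, 666)]
    )
    def test_total_is_64w_plus_26(self, w, total):
        assert len(build_catalog(WindowConfig(w))) == total

    def test_family_counts_w8(self):
        counts = build_catalog(WindowConfig(8)).family_counts()
        assert counts == {
            "pssm": 340, "disorder": 17, "ss": 51, "sa": 34, "aaf": 80, "freq": 16
        }
        assert sum(counts.values()) == 538

    def test_descriptors_unique_and_center_excluded(self):
        catalog = build_catalog(WindowConfig(8))
        assert len(set(catalog.descriptors)) == len(catalog)
        center = 9
        for d in catalog:
            if d.family in ("aaf", "freq"):
                assert d.offset != center

    def test_name_roundtrip(self):
        catalog = build_catalog(WindowConfig(7))
        from pyruvoylsite.features import FeatureCatalog

        assert FeatureCatalog.from_names(catalog.names()) == catalog


def _window(residues, label="positive", protein_id="P", center_pos=1):
    return PeptideWindow(protein_id, center_pos, residues, label)


class TestFrequencyTable:
    def test_unanimous_symbol_gets_frequency_one(self):
        config = WindowConfig(2)
        windows = [_window("AGSAA"), _window("CGSAC")]
        freq = fit_frequency_table(windows, config)
        assert freq.frequency(2, "G") == 1.0  # offset w (pre-center)
        assert freq.frequency(2, "A") == 0.0

    def test_frequencies_sum_to_one_per_offset(self):
        config = WindowConfig(2)
        windows = [_window("AGSAA"), _window("XXSAC"), _window("TTSGG")]
        freq = fit_frequency_table(windows, config)
        for off in (1, 2, 4, 5):
            assert sum(freq.table[off].values()) == pytest.approx(1.0, abs=1e-9)

    def test_requires_positive_windows(self):
        config = WindowConfig(2)
        with pytest.raises(ValueError, match="no positive"):
            fit_frequency_table([_window("AGSAA", label="negative")], config)

    def test_planted_bias_recovered(self):
        """80% G planted at the pre-center offset is recovered within 3 SE."""
        rng = np.random.default_rng(5)
        n = 200
        windows = []
        for _ in range(n):
            pre = "G" if rng.random() < 0.8 else "A"
            windows.append(_window(f"C{pre}SAA"))
        freq = fit_frequency_table(windows, WindowConfig(2))
        se = np.sqrt(0.8 * 0.2 / n)
        assert abs(freq.frequency(2, "G") - 0.8) < 3 * se

    def test_fit_on_all_windows_option(self):
        config = WindowConfig(2)
        windows = [_window("AGSAA"), _window("CCSAA", label="negative")]
        freq = fit_frequency_table(windows, config, on="all")
        assert freq.frequency(2, "G") == 0.5


@pytest.fixture(scope="module")
def encoded(small_bundle):
    config = WindowConfig(8)
    windows = build_sample_set(small_bundle.proteins, small_bundle.sites, config)
    freq = fit_frequency_table(windows, config)
    catalog = build_catalog(config)
    matrix = encode_all(windows, small_bundle.annotations, freq, catalog)
    return windows, freq, catalog, matrix


class TestEncoding:
    def test_matrix_shape_and_alignment(self, encoded, small_bundle):
        windows, freq, catalog, matrix = encoded
        assert matrix.values.shape == (len(windows), 538)
        row = encode_window(windows[3], small_bundle.annotations[windows[3].protein_id], freq, catalog)
        np.testing.assert_array_equal(matrix.values[3], row)

    def test_ss_sa_onehot_sums(self, encoded):
        """One-hot bits sum to 1 on real residues, 0 on padded ones."""
        windows, freq, catalog, matrix = encoded
        names = catalog.names()
        for off in (1, 9, 17):
            ss_cols = [names.index(f"ss|o{off}|{s}") for s in ("helix", "other", "strand")]
            sa_cols = [names.index(f"sa|o{off}|{s}") for s in ("buried", "exposed")]
            for i, x in enumerate(windows):
                padded = x.residues[off - 1] == "X"
                assert matrix.values[i, ss_cols].sum() == (0.0 if padded else 1.0)
                assert matrix.values[i, sa_cols].sum() == (0.0 if padded else 1.0)

    def test_padded_sites_contribute_zeros(self, encoded):
        """A padded site yields 26 zeros across pssm+disorder+ss+sa (+aaf)."""
        windows, freq, catalog, matrix = encoded
        padded = [
            (i, off)
            for i, x in enumerate(windows)
            for off in range(1, 18)
            if x.residues[off - 1] == "X"
        ]
        assert padded, "corpus should contain padded windows"
        for i, off in padded[:25]:
            for j, d in enumerate(catalog):
                if d.offset == off and d.family != "freq":
                    assert matrix.values[i, j] == 0.0

    def test_freq_feature_is_table_lookup(self, encoded):
        windows, freq, catalog, matrix = encoded
        names = catalog.names()
        j = names.index("freq|o8")
        for i, x in enumerate(windows[:40]):
            assert matrix.values[i, j] == freq.frequency(8, x.residues[7])

    def test_atchley_lookup(self, encoded):
        windows, freq, catalog, matrix = encoded
        names = catalog.names()
        j = names.index("aaf|o1|polarity")
        for i, x in enumerate(windows[:40]):
            expected = ATCHLEY_FACTORS[x.residues[0]]["polarity"]
            assert matrix.values[i, j] == expected

    def test_deterministic(self, encoded, small_bundle):
        windows, freq, catalog, _ = encoded
        x = windows[0]
        ann = small_bundle.annotations[x.protein_id]
        np.testing.assert_array_equal(
            encode_window(x, ann, freq, catalog), encode_window(x, ann, freq, catalog)
        )

    def test_empty_window_list_rejected(self, encoded, small_bundle):
        _, freq, catalog, _ = encoded
        with pytest.raises(ValueError, match="no windows"):
            encode_all([], small_bundle.annotations, freq, catalog)

    def test_missing_annotation_names_sample(self, encoded):
        _, freq, catalog, _ = encoded
        stray = _window("A" * 8 + "S" + "A" * 8, protein_id="NOPE", center_pos=9)
        with pytest.raises(ValueError, match="NOPE"):
            encode_all([stray], {}, freq, catalog)
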