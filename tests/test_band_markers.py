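import numpy as np
import pytest

from conftest import GEN_REGION, pipeline_markers
from ftirdry.band_markers import (
    Band,
    MarkerSet,
    classify_conformation,
    detect_bands,
    extract_markers,
    phosphate_ratio,
)
from ftirdry.preprocess import normalized_second_derivative, second_derivative
from ftirdry.spectral_core import FINGERPRINT, SpectralRegion, Spectrum
from ftirdry.synthetic import (
    DegradationSpec,
    FormulationSpec,
    degrade,
    generate_component,
    generate_formulation,
)


def band(pos, intensity=1.0, prom=1.0):
    return Band(position=pos, intensity=intensity, prominence=prom)


class TestDetectBands:
    def test_single_gaussian_one_band(self, gaussian_spectrum):
        d = second_derivative(gaussian_spectrum(center=1100.0))
        bands = detect_bands(d, SpectralRegion(950, 1450))
        assert len(bands) == 1
        assert abs(bands[0].position - 1100.0) <= 1.0

    def test_flat_spectrum_empty(self):
        s = Spectrum(np.arange(900.0, 1500.0), np.full(600, 0.3))
        bands = detect_bands(second_derivative(s), SpectralRegion(950, 1450))
        assert bands == []

    def test_trehalose_exactly_five(self):
        s = generate_component("trehalose_dry", 1.0, GEN_REGION)
        d = normalized_second_derivative(s, FINGERPRINT)
        bands = detect_bands(d, SpectralRegion(960, 1170))
        assert len(bands) == 5

    def test_positions_scale_invariant(self, gaussian_spectrum):
        s = gaussian_spectrum(center=1234.0)
        big = Spectrum(s.wavenumbers, 55.0 * s.absorbance)
        p1 = [b.position for b in detect_bands(second_derivative(s), SpectralRegion(950, 1450))]
        p2 = [b.position for b in detect_bands(second_derivative(big), SpectralRegion(950, 1450))]
        assert p1 == p2

    def test_edge_only_region_errors(self, gaussian_spectrum):
        d = second_derivative(gaussian_spectrum(lo=900.0, hi=1500.0))
        with pytest.raises(ValueError, match="edge-invalid"):
            detect_bands(d, SpectralRegion(900, 905))

    def test_sorted_ascending(self):
        s = generate_component("dsDNA_A", 1.0, GEN_REGION)
        d = normalized_second_derivative(s, FINGERPRINT)
        pos = [b.position for b in detect_bands(d, SpectralRegion(940, 1270))]
        assert pos == sorted(pos)


class TestExtractMarkers:
    def test_dried_dsdna_positions(self, dsdna_a_spectrum):
        m = pipeline_markers(dsdna_a_spectrum, "dried")
        assert abs(m.cc.position - 965) <= 1
        assert abs(m.co.position - 1050) <= 1
        assert abs(m.po2_sym.position - 1089) <= 1
        assert abs(m.po2_asym.position - 1235) <= 1

    def test_hydrated_dsdna_positions(self, dsdna_b_spectrum):
        m = pipeline_markers(dsdna_b_spectrum, "hydrated")
        assert abs(m.cc.position - 970) <= 1
        assert abs(m.co.position - 1052) <= 1
        assert abs(m.po2_asym.position - 1225) <= 1

    def test_albumin_only_all_absent(self):
        s = generate_component("albumin", 1.0, GEN_REGION)
        m = pipeline_markers(s, "dried")
        assert m.present() == {}

    def test_state_recorded(self, dsdna_a_spectrum):
        assert pipeline_markers(dsdna_a_spectrum, "dried").state_assumed == "dried"

    def test_bad_state_rejected(self, dsdna_a_spectrum):
        d = normalized_second_derivative(dsdna_a_spectrum, FINGERPRINT)
        with pytest.raises(ValueError, match="state"):
            extract_markers(d, state="soggy")

    def test_full_matrix_still_recovers_markers(self, full_matrix_spec):
        s = generate_formulation(full_matrix_spec(hydration=0.0), 1.0, GEN_REGION)
        m = pipeline_markers(s, "dried")
        assert m.po2_sym is not None and abs(m.po2_sym.position - 1089) <= 1
        assert m.po2_asym is not None and abs(m.po2_asym.position - 1235) <= 2


class TestPhosphateRatio:
    def test_equal_bands_give_unit_ratio(self):
        w = np.arange(900.0, 1501.0)
        a = np.exp(-4 * np.log(2) * (w - 1089.0) ** 2 / 18.0**2)
        a += np.exp(-4 * np.log(2) * (w - 1235.0) ** 2 / 18.0**2)
        m = pipeline_markers(Spectrum(w, a), "dried")
        assert phosphate_ratio(m).ratio == pytest.approx(1.0, abs=1e-6)

    def test_positions_recorded(self, dsdna_a_spectrum):
        m = pipeline_markers(dsdna_a_spectrum, "dried")
        r = phosphate_ratio(m)
        assert r.asym_position_used == m.po2_asym.position
        assert r.sym_position_used == m.po2_sym.position

    def test_missing_band_named(self):
        m = MarkerSet(po2_asym=band(1235.0))
        with pytest.raises(ValueError, match="po2_sym"):
            phosphate_ratio(m)

    def test_ratio_increases_when_degradation_lowers_sym(self):
        base = generate_formulation(
            FormulationSpec({"dsDNA": 1.0}, hydration=0.0), 1.0, GEN_REGION
        )
        hot = degrade(
            base,
            DegradationSpec(severity=0.8, affected_bands=(1089.0,),
                            amplitude_drift=-0.4, center_drift=0.0, seed=5),
        )
        r_base = phosphate_ratio(pipeline_markers(base, "dried")).ratio
        r_hot = phosphate_ratio(pipeline_markers(hot, "dried")).ratio
        assert r_hot > r_base


class TestClassifyConformation:
    def test_a_like_votes(self):
        m = MarkerSet(cc=band(965), co=band(1050), po2_asym=band(1235))
        assert classify_conformation(m) == "A_like"

    def test_b_votes(self):
        m = MarkerSet(cc=band(970), co=band(1052), po2_asym=band(1225))
        assert classify_conformation(m) == "B"

    def test_single_marker_indeterminate(self):
        assert classify_conformation(MarkerSet(cc=band(965))) == "indeterminate"

    def test_asym_gap_abstains(self):
        m = MarkerSet(cc=band(965), co=band(1052), po2_asym=band(1229))
        assert classify_conformation(m) == "indeterminate"

    def test_generated_endpoints(self, full_matrix_spec):
        for hydration, expected in ((1.0, "B"), (0.0, "A_like")):
            s = generate_formulation(
                FormulationSpec({"dsDNA": 1.0}, hydration=hydration), 1.0, GEN_REGION
            )
            state = "hydrated" if hydration == 1.0 else "dried"
            assert classify_conformation(pipeline_markers(s, state)) == expected

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_full_matrix_with_noise(self, full_matrix_spec, seed):
        # noise_sd at ~10% of the smallest dsDNA band amplitude (0.4)
        s = generate_formulation(full_matrix_spec(0.0, noise_sd=0.04, seed=seed),
                                 1.0, GEN_REGION)
        assert classify_conformation(pipeline_markers(s, "dried")) == "A_like"
        s = generate_formulation(full_matrix_spec(1.0, noise_sd=0.04, seed=seed),
                                 1.0, GEN_REGION)
        assert classify_conformation(pipeline_markers(s, "hydrated")) == "B"


class TestRehydrationRoundTrip:
    def test_markers_reversible(self):
        fresh = generate_formulation(
            FormulationSpec({"dsDNA": 1.0}, hydration=1.0), 1.0, GEN_REGION
        )
        dried = generate_formulation(
            FormulationSpec({"dsDNA": 1.0}, hydration=0.0), 1.0, GEN_REGION
        )
        rehydrated = generate_formulation(
            FormulationSpec({"dsDNA": 1.0}, hydration=1.0), 1.0, GEN_REGION
        )
        m_fresh = pipeline_markers(fresh, "hydrated")
        m_dried = pipeline_markers(dried, "dried")
        m_re = pipeline_markers(rehydrated, "hydrated")
        for name in ("cc", "co", "po2_asym"):
            assert getattr(m_fresh, name).position == getattr(m_re, name).position
        assert m_dried.po2_asym.position != m_fresh.po2_asym.position
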