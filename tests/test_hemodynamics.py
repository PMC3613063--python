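"""AIF selection, rCBV, truncated-SVD deconvolution, TTP and MTT."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dscquant import constants
from dscquant.hemodynamics import (
    DeconvolutionConfig,
    build_convolution_operator,
    compute_mtt,
    compute_rcbf,
    compute_rcbv,
    compute_ttp,
    deconvolve,
    select_aif_auto,
)
from dscquant.phantom import (
    PhantomConfig,
    build_phantom,
    gamma_variate_aif,
    synthesize_tissue_curve,
)
from dscquant.types import (
    ArterialInputFunction,
    ConcentrationSeries,
    ParametricMap,
    TissueLabel,
)

T = np.arange(70.0)
AIF = gamma_variate_aif(T, 0.6, 10.0, 3.0, 1.5)


def _conc_from_curves(curves, tr=1.0, te=0.04):
    """Pack 1-D curves into a (n, 1, 1, t) concentration series."""
    data = np.stack(curves)[:, None, None, :]
    return ConcentrationSeries(
        data=data, baseline=np.ones(data.shape[:3]), tr=tr, te=te
    )


def _aif(curve=AIF):
    return ArterialInputFunction(curve, source_voxels=[], method="MANUAL")


class TestAifSelection:
    def test_recovers_true_aif_from_arterial_voxels(self):
        # vessel voxels carry the undispersed arterial curve
        run = build_phantom(
            PhantomConfig(noise_sigma=0.0, vessel_carries_aif=True)
        )
        from dscquant.preprocess import (
            compute_baseline,
            compute_brain_mask,
            signal_to_concentration,
        )

        brain = compute_brain_mask(run.series)
        conc = signal_to_concentration(run.series, compute_baseline(run.series))
        aif = select_aif_auto(conc, brain)
        assert aif.curve.max() == pytest.approx(run.aif_true.max(), rel=0.05)
        assert np.argmax(aif.curve) == np.argmax(run.aif_true)

    def test_manual_voxel_list_bypasses_scoring(self, noise_free_run):
        conc = noise_free_run.conc
        voxels = [(10, 10, 0), (10, 11, 0)]
        aif = select_aif_auto(conc, noise_free_run.brain, voxels=voxels)
        expected = (conc.data[10, 10, 0] + conc.data[10, 11, 0]) / 2.0
        assert aif.method == "MANUAL"
        assert np.allclose(aif.curve, expected)

    def test_k_larger_than_candidates_uses_all(self, noise_free_run):
        aif = select_aif_auto(noise_free_run.conc, noise_free_run.brain, k=10**6)
        assert len(aif.source_voxels) <= noise_free_run.brain.count

    def test_no_positive_peak_rejected(self, noise_free_run):
        conc = ConcentrationSeries(
            data=np.zeros((4, 4, 1, 70)), baseline=np.ones((4, 4, 1)),
            tr=1.0, te=0.04,
        )
        from dscquant.types import MaskLabel, VoxelMask

        mask = VoxelMask(np.ones((4, 4, 1), bool), MaskLabel.BRAIN)
        with pytest.raises(ValueError):
            select_aif_auto(conc, mask)


class TestRcbv:
    def test_tissue_equal_to_aif_gives_kh_over_rho(self):
        conc = _conc_from_curves([AIF])
        rcbv = compute_rcbv(conc, _aif())
        assert rcbv.data[0, 0, 0] == pytest.approx(0.705)

    def test_zero_concentration_gives_zero(self):
        conc = _conc_from_curves([np.zeros_like(AIF)])
        assert compute_rcbv(conc, _aif()).data[0, 0, 0] == 0.0

    def test_linearity(self):
        conc = _conc_from_curves([2.0 * AIF])
        assert compute_rcbv(conc, _aif()).data[0, 0, 0] == pytest.approx(1.410)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100.0, allow_nan=False))
    def test_common_scale_invariance(self, scale):
        tissue = synthesize_tissue_curve(AIF, 4.0, 50.0, 0.0, 1.0)
        a = compute_rcbv(_conc_from_curves([tissue]), _aif()).data[0, 0, 0]
        b = compute_rcbv(
            _conc_from_curves([tissue * scale]), _aif(AIF * scale)
        ).data[0, 0, 0]
        assert b == pytest.approx(a, rel=1e-9)

    def test_zero_aif_integral_rejected(self):
        with pytest.raises(ValueError):
            compute_rcbv(_conc_from_curves([AIF]), _aif(np.r_[1.0, np.zeros(69)]))


class TestConvolutionOperator:
    def test_impulse_aif_gives_scaled_identity(self):
        impulse = np.zeros(16)
        impulse[0] = 1.0
        cfg = DeconvolutionConfig(method="sSVD", tr=1.0)
        A = build_convolution_operator(impulse, cfg)
        assert np.allclose(A, constants.RHO_OVER_KH * np.eye(16))

    def test_forward_model_equivalence_with_phantom(self):
        # operator @ residue must reproduce the generator's tissue curve
        cfg = DeconvolutionConfig(method="sSVD", tr=1.0)
        A = build_convolution_operator(AIF, cfg)
        mtt = 4.0 / 50.0 * 60.0
        flow = (50.0 / 60.0) * (1.0 - np.exp(-1.0 / mtt)) * mtt
        f = flow * np.exp(-T / mtt)
        tissue = synthesize_tissue_curve(AIF, 4.0, 50.0, 0.0, 1.0)
        assert np.allclose(A @ f, tissue, atol=1e-12)

    def test_circulant_operator_reproduces_padded_aif_cyclically(self):
        cfg = DeconvolutionConfig(method="cSVD", tr=1.0, pad_factor=2)
        A = build_convolution_operator(AIF, cfg)
        delta = np.zeros(140)
        delta[0] = 1.0
        col = A @ delta
        assert np.allclose(col[:70], constants.RHO_OVER_KH * AIF)
        shifted = np.roll(delta, 5)
        assert np.allclose(A @ shifted, np.roll(col, 5))


class TestDeconvolve:
    @pytest.mark.parametrize("method", ["sSVD", "cSVD"])
    def test_aif_by_itself_yields_kh_over_rho_delta(self, method):
        # at a truncation fraction appropriate to noise-free data the
        # recovered curve is a delta of height k_H/rho at t = 0
        cfg = DeconvolutionConfig(method=method, tr=1.0, truncation_fraction=1e-4)
        A = build_convolution_operator(AIF, cfg)
        f = deconvolve(AIF, A, cfg)
        assert f.max() == pytest.approx(0.705, rel=0.01)
        assert np.argmax(f) == 0

    def test_truncated_solution_matches_projection_oracle(self):
        # independent oracle: project the exact solution onto the retained
        # right-singular subspace of the operator
        cfg = DeconvolutionConfig(method="sSVD", tr=1.0)  # default 0.20
        A = build_convolution_operator(AIF, cfg)
        tissue = synthesize_tissue_curve(AIF, 4.0, 50.0, 0.0, 1.0)
        f = deconvolve(tissue, A, cfg)
        u, s, vt = np.linalg.svd(A)
        keep = s >= cfg.truncation_fraction * s[0]
        f_exact = np.linalg.pinv(A) @ tissue
        f_proj = vt[keep].T @ (vt[keep] @ f_exact)
        assert np.allclose(f, f_proj, atol=1e-8)

    def test_noise_free_gm_recovery(self):
        # small truncation on noise-free curves: max f recovers the
        # generating discrete flow amplitude within 10%
        tissue = synthesize_tissue_curve(AIF, 4.0, 50.0, 0.0, 1.0)
        mtt = 4.0 / 50.0 * 60.0
        flow = (50.0 / 60.0) * (1.0 - np.exp(-1.0 / mtt)) * mtt
        cfg = DeconvolutionConfig(method="sSVD", tr=1.0, truncation_fraction=0.05)
        A = build_convolution_operator(AIF, cfg)
        assert deconvolve(tissue, A, cfg).max() == pytest.approx(flow, rel=0.10)

    def test_zero_curve_gives_zero(self):
        cfg = DeconvolutionConfig(method="sSVD", tr=1.0)
        A = build_convolution_operator(AIF, cfg)
        assert np.allclose(deconvolve(np.zeros(70), A, cfg), 0.0)

    def test_degenerate_operator_rejected(self):
        # a zero AIF yields a zero operator: every singular value falls
        # below any threshold and no component can be inverted
        cfg = DeconvolutionConfig(method="sSVD", tr=1.0)
        A = build_convolution_operator(np.zeros(70), cfg)
        with pytest.raises(ValueError):
            deconvolve(AIF, A, cfg)

    def test_forward_inverse_consistency(self):
        # convolving the recovered f reproduces the noise-free tissue
        # curve within a truncation-controlled bound
        tissue = synthesize_tissue_curve(AIF, 4.0, 50.0, 0.0, 1.0)
        cfg = DeconvolutionConfig(method="sSVD", tr=1.0, truncation_fraction=1e-4)
        A = build_convolution_operator(AIF, cfg)
        f = deconvolve(tissue, A, cfg)
        resid = np.linalg.norm(A @ f - tissue) / np.linalg.norm(tissue)
        assert resid < 1e-8

    def test_ssvd_and_csvd_agree_on_zero_delay_noise_free_curves(self):
        tissue = synthesize_tissue_curve(AIF, 4.0, 50.0, 0.0, 1.0)
        out = {}
        for method in ("sSVD", "cSVD"):
            cfg = DeconvolutionConfig(method=method, tr=1.0, truncation_fraction=1e-3)
            A = build_convolution_operator(AIF, cfg)
            out[method] = deconvolve(tissue, A, cfg).max()
        assert out["cSVD"] == pytest.approx(out["sSVD"], rel=0.10)


class TestRcbf:
    def test_delayed_voxels_favour_csvd(self):
        delayed = synthesize_tissue_curve(AIF, 4.0, 50.0, 2.0, 1.0)
        conc = _conc_from_curves([delayed])
        out = {}
        for method in ("sSVD", "cSVD"):
            cfg = DeconvolutionConfig(method=method, tr=1.0)
            out[method] = compute_rcbf(conc, _aif(), cfg).data[0, 0, 0]
        assert out["cSVD"] >= out["sSVD"]

    def test_zero_concentration_voxel(self):
        conc = _conc_from_curves([np.zeros_like(AIF)])
        cfg = DeconvolutionConfig(method="sSVD", tr=1.0)
        assert compute_rcbf(conc, _aif(), cfg).data[0, 0, 0] == 0.0

    def test_linearity_in_tissue_amplitude(self):
        tissue = synthesize_tissue_curve(AIF, 4.0, 50.0, 0.0, 1.0)
        conc1 = _conc_from_curves([tissue])
        conc2 = _conc_from_curves([2.0 * tissue])
        cfg = DeconvolutionConfig(method="sSVD", tr=1.0)
        a = compute_rcbf(conc1, _aif(), cfg).data[0, 0, 0]
        b = compute_rcbf(conc2, _aif(), cfg).data[0, 0, 0]
        assert b == pytest.approx(2.0 * a, rel=1e-9)

    def test_class_rank_order_preserved_on_phantom(self, noise_free_run):
        run = noise_free_run
        masks = run.dataset.truth_masks
        for m in ("sSVD", "cSVD"):
            data = run.rcbf[m].data
            assert data[masks[TissueLabel.VESSEL].data].min() > data[
                masks[TissueLabel.GM].data
            ].max()
            assert data[masks[TissueLabel.GM].data].min() > data[
                masks[TissueLabel.WM].data
            ].max()


class TestTtp:
    def test_peak_index_to_seconds_convention(self):
        curve = np.zeros(70)
        curve[24] = 5.0  # 25th dynamic in 1-based counting
        conc = _conc_from_curves([curve])
        assert compute_ttp(conc).data[0, 0, 0] == pytest.approx(24.0)

    def test_uniform_delay_shifts_ttp(self):
        base = synthesize_tissue_curve(AIF, 4.0, 50.0, 0.0, 1.0)
        delayed = synthesize_tissue_curve(AIF, 4.0, 50.0, 5.0, 1.0)
        conc = _conc_from_curves([base, delayed])
        ttp = compute_ttp(conc).data
        assert ttp[1, 0, 0] - ttp[0, 0, 0] == pytest.approx(5.0)

    def test_flat_curve_flagged_at_window_start(self):
        conc = _conc_from_curves([np.zeros(70)])
        ttp = compute_ttp(conc)
        assert ttp.data[0, 0, 0] == pytest.approx(10.0)
        assert ttp.flags[0, 0, 0]

    def test_first_occurrence_wins_ties(self):
        curve = np.zeros(70)
        curve[[20, 30]] = 5.0
        conc = _conc_from_curves([curve])
        assert compute_ttp(conc).data[0, 0, 0] == pytest.approx(20.0)


class TestMtt:
    def test_central_volume_arithmetic(self):
        cbv = ParametricMap(np.full((1, 1, 1), 3.2), "CBV", "mL/100 g")
        cbf = ParametricMap(np.full((1, 1, 1), 40.0), "CBF", "mL/100 g/min")
        assert compute_mtt(cbv, cbf).data[0, 0, 0] == pytest.approx(4.8)

    def test_zero_cbv_gives_zero_mtt(self):
        cbv = ParametricMap(np.zeros((1, 1, 1)), "CBV", "mL/100 g")
        cbf = ParametricMap(np.full((1, 1, 1), 40.0), "CBF", "mL/100 g/min")
        assert compute_mtt(cbv, cbf).data[0, 0, 0] == 0.0

    def test_low_flow_voxels_flagged(self):
        cbv = ParametricMap(np.full((1, 1, 1), 2.0), "CBV", "mL/100 g")
        cbf = ParametricMap(np.zeros((1, 1, 1)), "CBF", "mL/100 g/min")
        mtt = compute_mtt(cbv, cbf)
        assert mtt.data[0, 0, 0] == 0.0
        assert mtt.flags[0, 0, 0]

    def test_phantom_mtt_recovery(self, noise_free_run):
        # scaled maps: recovered MTT within 15% of the 4.8 s ground truth
        run = noise_free_run
        gm = run.dataset.truth_masks[TissueLabel.GM].data
        mtt = run.absolute["MTT_sSVD"].data[gm].mean()
        assert mtt == pytest.approx(4.8, rel=0.15)

    def test_grid_mismatch_rejected(self):
        cbv = ParametricMap(np.zeros((2, 2, 1)), "CBV", "mL/100 g")
        cbf = ParametricMap(np.zeros((3, 3, 1)), "CBF", "mL/100 g/min")
        with pytest.raises(ValueError):
            compute_mtt(cbv, cbf)
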