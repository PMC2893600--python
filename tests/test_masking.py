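"""The defined-percentage retention rule and mask construction."""

import numpy as np
import pytest

from xmask.io import MaskFile, SchemaError
from xmask.masking import (
    DEFAULT_THRESHOLDS,
    MaskRuleParams,
    apply_mask,
    build_isv_mask,
    build_sfp_mask,
    build_threshold_series,
    combine_masks,
    compute_mask_percentage,
)
from conftest import make_matrix, make_sheet


@pytest.mark.parametrize("ts,r,s,expected", [
    (12, 3, 4, 0.83),   # the 2 genotypes x 2 tissues x 3 replicates design
    (12, 1, 12, 1.00),  # kept if any sample reaches the threshold
    (6, 3, 2, 0.67),
])
def test_mask_percentage(ts, r, s, expected):
    assert compute_mask_percentage(ts, r, s) == expected


def test_mask_percentage_rejects_bad_design():
    with pytest.raises(ValueError):
        compute_mask_percentage(12, 13, 1)
    with pytest.raises(ValueError):
        compute_mask_percentage(12, 0, 1)


def test_params_from_sheet():
    p = MaskRuleParams.from_sample_sheet(make_sheet(), "target")
    assert (p.ts, p.r, p.s, p.p) == (12, 3, 4, 0.83)


def test_isv_mask_boundaries():
    params = MaskRuleParams(ts=12, r=3, s=4)
    rows = np.full((3, 12), 10.0)
    rows[0, :] = 100.0           # above threshold everywhere -> retained
    rows[1, :2] = 100.0          # above in exactly R-1 samples -> masked
    rows[2, :3] = 100.0          # above in exactly R samples -> retained
    m = make_matrix(rows)
    mask = build_isv_mask(m, 50.0, params)
    assert mask.masked_probe_ids == {"p001"}
    assert mask.provenance == "ISV" and mask.percentage_p == 0.83
    # threshold 0 masks nothing on positive intensities
    assert len(build_isv_mask(m, 0.0, params)) == 0


def test_isv_mask_checks_design_consistency():
    m = make_matrix(np.full((2, 12), 5.0))
    with pytest.raises(SchemaError):
        build_isv_mask(m, 1.0, MaskRuleParams(ts=6, r=3, s=2))


def test_threshold_series_default_length_nested_and_bruteforce():
    """16 default masks, nested in threshold, equal to a per-probe recount."""
    rng = np.random.default_rng(21)
    m = make_matrix(rng.lognormal(5, 1.5, (10_000, 12)))
    params = MaskRuleParams(ts=12, r=3, s=4)
    masks = build_threshold_series(m, None, params)
    assert len(masks) == len(DEFAULT_THRESHOLDS) == 16
    for a, b in zip(masks, masks[1:]):
        assert a.masked_probe_ids <= b.masked_probe_ids
    # independent brute-force recount, probe by probe
    X = m.values.to_numpy()
    ids = m.probe_ids.to_numpy()
    for mask in masks[::5]:
        expect = {ids[i] for i in range(len(ids))
                  if sum(v >= mask.threshold for v in X[i]) < params.r}
        assert mask.masked_probe_ids == expect


def test_threshold_series_rejects_unsorted():
    m = make_matrix(np.full((2, 12), 5.0))
    with pytest.raises(ValueError):
        build_threshold_series(m, [10, 5], MaskRuleParams(ts=12, r=3, s=4))


def test_sfp_mask_drops_unknown_and_duplicates():
    universe = ["p1", "p2", "p3"]
    with pytest.warns(UserWarning, match="absent"):
        mask = build_sfp_mask(["p1", "p2", "nope"], universe)
    assert mask.masked_probe_ids == {"p1", "p2"}
    assert mask.provenance == "SFP"
    dup = build_sfp_mask(["p1", "p1", "p2"], universe)
    assert dup.masked_probe_ids == {"p1", "p2"}
    with pytest.warns(UserWarning, match="empty"):
        assert len(build_sfp_mask([], universe)) == 0


def test_combine_masks_union():
    a = MaskFile(frozenset({"p1", "p2"}), 40.0, 0.83, "ISV")
    b = MaskFile(frozenset({"p2", "p3"}), 0.0, 1.0, "SFP")
    c = combine_masks(a, b)
    assert c.masked_probe_ids == {"p1", "p2", "p3"}
    assert c.provenance == "combined"
    empty = MaskFile(frozenset(), 0.0, 1.0, "SFP")
    assert combine_masks(a, empty).masked_probe_ids == a.masked_probe_ids
    assert len(c) <= len(a) + len(b)


def test_apply_mask():
    m = make_matrix(np.arange(1, 37).reshape(3, 12))
    empty = MaskFile(frozenset(), 0.0, 1.0, "ISV")
    assert apply_mask(m, empty).values.equals(m.values)
    partial = MaskFile(frozenset({"p001", "zzz"}), 0.0, 1.0, "ISV")
    out = apply_mask(m, partial)
    assert out.n_probes == m.n_probes - 1 and "p001" not in out.probe_ids
    full = MaskFile(frozenset(m.probe_ids), 0.0, 1.0, "ISV")
    with pytest.warns(UserWarning, match="every probe"):
        assert apply_mask(m, full).n_probes == 0


def test_double_mask_on_synthetic_removes_planted_probes(small_sim):
    """Double-masking removes all planted SFP probes and every ISV probe
    whose intensity falls below threshold in enough samples."""
    from xmask.preprocess import background_correct, quantile_normalize

    nt = quantile_normalize(background_correct(small_sim.target))
    params = MaskRuleParams.from_sample_sheet(nt.samples, "target")
    isv_mask = build_isv_mask(nt, 40.0, params)
    sfp_mask = build_sfp_mask(small_sim.sfp_list, nt.probe_ids)
    double = combine_masks(isv_mask, sfp_mask)
    assert set(small_sim.sfp_list) <= double.masked_probe_ids
    assert isv_mask.masked_probe_ids <= double.masked_probe_ids
    # probe-set attrition from adding the SFP mask is bounded by the number
    # of SFP-carrying probe sets
    probeset_of = small_sim.pmap.probeset_of()
    lost = {probeset_of[p] for p in double.masked_probe_ids} - {
        probeset_of[p] for p in isv_mask.masked_probe_ids}
    assert len(lost) <= len(small_sim.truth.sfp_genes)
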