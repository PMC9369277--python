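"""Vessel extraction, maturity calls, densities and specimen pooling."""
import numpy as np
import pytest

from adenoquant.quantify import (
    VesselObject,
    aggregate_specimen,
    classify_maturity,
    compute_densities,
    extract_vessels,
    DensityRecord,
)
from adenoquant.segmentation import (
    BinaryMask,
    CompartmentMasks,
    build_compartment_masks,
    label_objects,
)
from adenoquant.pipeline import quantify_field, segment_field


def _ring(shape, row, col, r_out, r_in):
    yy, xx = np.ogrid[:shape[0], :shape[1]]
    d = np.hypot(yy - row, xx - col)
    return (d <= r_out) & (d > r_in)


def _simple_compartments(shape, stroma=True):
    full = np.ones(shape, bool)
    empty = np.zeros(shape, bool)
    bm = lambda px, n: BinaryMask(px, n, "derived", float("nan"))
    if stroma:
        return CompartmentMasks(bm(full, "stroma"), bm(empty, "glands"),
                                bm(empty, "myometrium"), bm(empty, "background"))
    return CompartmentMasks(bm(empty, "stroma"), bm(empty, "glands"),
                            bm(full, "myometrium"), bm(empty, "background"))


class TestExtractVessels:
    def test_cd31_ring_without_podoplanin_is_blood(self):
        shape = (60, 60)
        cd31 = _ring(shape, 30, 30, 8, 5)
        objs = label_objects(BinaryMask(cd31, "CD31", "fixed", 0), 8)
        pdpn = BinaryMask(np.zeros(shape, bool), "PDPN", "fixed", 0)
        vessels = extract_vessels(objs, pdpn, _simple_compartments(shape), 1.0)
        assert len(vessels) == 1 and vessels[0].vessel_class == "blood"
        assert vessels[0].pdpn_overlap == 0.0

    def test_podoplanin_only_ring_is_lymph(self):
        shape = (60, 60)
        pdpn = _ring(shape, 30, 30, 8, 5)
        empty = label_objects(BinaryMask(np.zeros(shape, bool), "CD31", "fixed", 0), 8)
        vessels = extract_vessels(empty, BinaryMask(pdpn, "PDPN", "fixed", 0),
                                  _simple_compartments(shape), 1.0)
        assert len(vessels) == 1 and vessels[0].vessel_class == "lymph"

    def test_double_positive_ring_counts_once_as_lymph(self):
        shape = (60, 60)
        ring = _ring(shape, 30, 30, 8, 5)
        objs = label_objects(BinaryMask(ring, "CD31", "fixed", 0), 8)
        vessels = extract_vessels(objs, BinaryMask(ring, "PDPN", "fixed", 0),
                                  _simple_compartments(shape), 1.0)
        assert len(vessels) == 1 and vessels[0].vessel_class == "lymph"

    def test_min_area_filter_drops_specks(self):
        shape = (30, 30)
        speck = np.zeros(shape, bool)
        speck[5, 5] = True
        objs = label_objects(BinaryMask(speck, "CD31", "fixed", 0), 8)
        pdpn = BinaryMask(np.zeros(shape, bool), "PDPN", "fixed", 0)
        vessels = extract_vessels(objs, pdpn, _simple_compartments(shape), 1.0,
                                  min_area_um2=5.0)
        assert vessels == []

    def test_counts_match_ground_truth_per_compartment(self, ectopic_field,
                                                       segmented_ectopic,
                                                       pipeline_config):
        stack, gt = ectopic_field
        records, _ = quantify_field(stack, segmented_ectopic, pipeline_config.quantification)
        for r in records:
            assert r.blood_count == gt.count("blood", r.compartment)
            assert r.lymph_count == gt.count("lymph", r.compartment)


class TestMaturity:
    def _match_truth(self, vessels, gt):
        """Pair each detected blood vessel with the nearest planted one."""
        pairs = []
        for v in vessels:
            if v.vessel_class != "blood":
                continue
            best = min(
                (p for p in gt.vessels if p.vessel_class == "blood"),
                key=lambda p: (p.row - v.centroid[0]) ** 2 + (p.col - v.centroid[1]) ** 2,
            )
            pairs.append((v, best))
        return pairs

    def test_matches_planted_flags(self, eutopic_field, quantified_eutopic):
        _, gt = eutopic_field
        _, vessels = quantified_eutopic
        pairs = self._match_truth(vessels, gt)
        assert pairs
        for detected, planted in pairs:
            assert detected.is_mature == planted.has_asma_ring

    def test_no_asma_anywhere_means_immature(self):
        shape = (60, 60)
        cd31 = _ring(shape, 30, 30, 8, 5)
        objs = label_objects(BinaryMask(cd31, "CD31", "fixed", 0), 8)
        pdpn = BinaryMask(np.zeros(shape, bool), "PDPN", "fixed", 0)
        v = extract_vessels(objs, pdpn, _simple_compartments(shape), 1.0)[0]
        v = classify_maturity(v, BinaryMask(np.zeros(shape, bool), "aSMA", "fixed", 0), 3)
        assert v.asma_boundary_overlap == 0.0 and v.is_mature is False

    def test_lymph_vessel_rejected(self):
        shape = (40, 40)
        pdpn = _ring(shape, 20, 20, 8, 5)
        empty = label_objects(BinaryMask(np.zeros(shape, bool), "CD31", "fixed", 0), 8)
        v = extract_vessels(empty, BinaryMask(pdpn, "PDPN", "fixed", 0),
                            _simple_compartments(shape), 1.0)[0]
        with pytest.raises(ValueError, match="blood"):
            classify_maturity(v, BinaryMask(np.zeros(shape, bool), "aSMA", "fixed", 0))


def _fake_vessel(i, comp="stroma", vessel_class="blood", mature=None):
    return VesselObject(
        label=i, vessel_class=vessel_class, area_um2=100.0, centroid=(0.0, 0.0),
        compartment=comp, bbox=(0, 0, 1, 1), footprint=np.ones((1, 1), bool),
        pdpn_overlap=0.0, is_mature=mature,
        asma_boundary_overlap=None if mature is None else float(mature),
    )


class TestComputeDensities:
    def _masks(self, n_stroma_px, shape):
        stroma = np.zeros(shape, bool)
        stroma.ravel()[:n_stroma_px] = True
        bm = lambda px, n: BinaryMask(px, n, "derived", float("nan"))
        return CompartmentMasks(bm(stroma, "stroma"), bm(np.zeros(shape, bool), "glands"),
                                bm(np.zeros(shape, bool), "myometrium"),
                                bm(~stroma, "background"))

    def test_density_arithmetic(self):
        # 5 blood vessels in 0.5 mm^2 of stroma -> 10 vessels/mm^2
        shape = (1000, 1000)  # 1 mm^2 at 1 µm/px
        masks = self._masks(500_000, shape)
        vessels = [_fake_vessel(i, mature=(i < 3)) for i in range(5)]
        empty = BinaryMask(np.zeros(shape, bool), "X", "fixed", 0)
        (rec,) = compute_densities(vessels, masks, empty, empty, 1.0)
        assert rec.bvd_vessels_per_mm2 == pytest.approx(10.0)
        assert rec.mature_ratio_fraction == pytest.approx(3 / 5)

    def test_pct_area_arithmetic(self):
        # CD31 covering 63,000 µm^2 of a 0.63 mm^2 compartment -> 10%
        shape = (700, 1000)
        masks = self._masks(630_000, shape)
        cd31 = np.zeros(shape, bool)
        cd31.ravel()[:63_000] = True
        empty = BinaryMask(np.zeros(shape, bool), "X", "fixed", 0)
        (rec,) = compute_densities([], masks, BinaryMask(cd31, "CD31", "fixed", 0),
                                   empty, 1.0)
        assert rec.pct_cd31_area_pct == pytest.approx(10.0)
        assert rec.blood_count == 0 and rec.mature_ratio_fraction is None

    def test_zero_area_compartment_suppressed(self):
        shape = (50, 50)
        masks = self._masks(2500, shape)  # stroma only, no myometrium
        empty = BinaryMask(np.zeros(shape, bool), "X", "fixed", 0)
        records = compute_densities([], masks, empty, empty, 1.0)
        assert [r.compartment for r in records] == ["stroma"]

    def test_rerun_is_pure(self, eutopic_field, segmented_eutopic, pipeline_config):
        stack, _ = eutopic_field
        r1, _ = quantify_field(stack, segmented_eutopic, pipeline_config.quantification)
        r2, _ = quantify_field(stack, segmented_eutopic, pipeline_config.quantification)
        assert r1 == r2

    def test_class_counts_conserve_total(self, ectopic_field, segmented_ectopic,
                                         pipeline_config):
        stack, _ = ectopic_field
        records, vessels = quantify_field(stack, segmented_ectopic,
                                          pipeline_config.quantification)
        for r in records:
            kept = [v for v in vessels if v.compartment == r.compartment]
            assert r.blood_count + r.lymph_count == len(kept)


def _record(bvd_count, area, sid="S", fid="f", comp="stroma", mature=None,
            pct_cd31=0.0, pct_pdpn=0.0, lymph=0):
    return DensityRecord(
        specimen_id=sid, field_id=fid, compartment=comp,
        compartment_area_mm2=area, blood_count=bvd_count, lymph_count=lymph,
        mature_count=mature, bvd_vessels_per_mm2=bvd_count / area,
        lvd_vessels_per_mm2=lymph / area, pct_cd31_area_pct=pct_cd31,
        pct_pdpn_area_pct=pct_pdpn,
        mature_ratio_fraction=None if mature is None or not bvd_count else mature / bvd_count,
    )


class TestAggregateSpecimen:
    def test_pooled_density_is_total_count_over_total_area(self):
        rows = aggregate_specimen([_record(2, 0.2, fid="f0"), _record(4, 0.4, fid="f1")])
        (row,) = rows
        assert row["bvd_vessels_per_mm2"] == pytest.approx((2 + 4) / (0.2 + 0.4))

    def test_single_field_is_identity(self):
        rec = _record(7, 0.35, mature=3, pct_cd31=4.2)
        (row,) = aggregate_specimen([rec])
        assert row["bvd_vessels_per_mm2"] == pytest.approx(rec.bvd_vessels_per_mm2)
        assert row["pct_cd31_area_pct"] == pytest.approx(4.2)
        assert row["mature_ratio_fraction"] == pytest.approx(3 / 7)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_specimen([])

    def test_pct_and_count_orderings_agree(self):
        """With vessel size held constant, %CD31 area ranks like BVD."""
        lo = [_record(3, 0.3, pct_cd31=1.0)]
        hi = [_record(9, 0.3, pct_cd31=3.0)]
        (lo_row,) = aggregate_specimen(lo)
        (hi_row,) = aggregate_specimen(hi)
        assert (hi_row["bvd_vessels_per_mm2"] > lo_row["bvd_vessels_per_mm2"]) == (
            hi_row["pct_cd31_area_pct"] > lo_row["pct_cd31_area_pct"])
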