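import numpy as np
import pytest

from ctanomaly import phantom as ph
from ctanomaly.report_ie import extract_organ_labels
from ctanomaly.schema import MASK_LABELS, ORGAN_CATEGORIES, TARGET_ORGANS


def high_prevalence_config(**kw):
    return ph.desk_scale_config(
        lesion_prevalence={
            o: {c: 0.6 for c in ORGAN_CATEGORIES[o]} for o in TARGET_ORGANS
        },
        **kw,
    )


class TestConfigValidation:
    def test_out_of_grid_organ_rejected(self):
        spec = ph.OrganSpec(center=(2.0, 16.0, 12.0), radii=(8.0, 4.0, 4.0), mean_hu=60)
        with pytest.raises(ValueError):  # surfaced through pydantic validation
            ph.PhantomConfig(grid_shape=(32, 32, 24), organ_specs={"liver": spec})

    def test_overlapping_organs_rejected(self):
        specs = {
            "liver": ph.OrganSpec(center=(16, 16, 12), radii=(6, 6, 6), mean_hu=60),
            "spleen": ph.OrganSpec(center=(18, 16, 12), radii=(6, 6, 6), mean_hu=50),
        }
        cfg = ph.PhantomConfig(grid_shape=(32, 32, 24), organ_specs=specs)
        with pytest.raises(ph.PhantomError):
            ph.base_arrays(cfg)

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError):
            ph.desk_scale_config(lesion_prevalence={"liver": {"mass": 1.5}})


class TestGenerateExam:
    def test_zero_prevalence_gives_empty_truth(self):
        cfg = ph.desk_scale_config(
            lesion_prevalence={o: {c: 0.0 for c in ORGAN_CATEGORIES[o]} for o in TARGET_ORGANS}
        )
        ex = ph.generate_exam(cfg, np.random.default_rng(0))
        assert all(len(v) == 0 for v in ex.truth_labels.values())

    def test_determinism_under_seed(self):
        cfg = high_prevalence_config()
        a = ph.generate_exam(cfg, np.random.default_rng(5))
        b = ph.generate_exam(cfg, np.random.default_rng(5))
        assert np.array_equal(a.volume, b.volume)
        assert np.array_equal(a.mask, b.mask)
        assert a.report_text == b.report_text
        assert a.truth_labels == b.truth_labels

    def test_certain_lesion_present_in_every_draw(self):
        # Bernoulli sampler at p=1: the liver lesion must appear in all draws
        prev = {o: {c: 0.0 for c in ORGAN_CATEGORIES[o]} for o in TARGET_ORGANS}
        prev["liver"]["mass"] = 1.0
        cfg = ph.desk_scale_config(lesion_prevalence=prev)
        rng = np.random.default_rng(0)
        for _ in range(200):
            ex = ph.generate_exam(cfg, rng)
            assert "mass" in ex.truth_labels["liver"]

    def test_lesion_voxels_inside_organ(self):
        cfg = high_prevalence_config(noise_sigma_hu=0.0)
        base_hu, mask = ph.base_arrays(cfg)
        rng = np.random.default_rng(3)
        found = False
        for _ in range(10):
            ex = ph.generate_exam(cfg, rng)
            delta = ex.volume - base_hu.astype(np.float32)
            for organ, cats in ex.truth_labels.items():
                if cats:
                    found = True
                changed = np.abs(delta) > 1e-3
                assert (mask[changed] > 0).all()  # lesions only inside organs
        assert found

    def test_truth_labels_iff_lesion_inserted(self):
        cfg = high_prevalence_config(noise_sigma_hu=0.0)
        base_hu, mask = ph.base_arrays(cfg)
        ex = ph.generate_exam(cfg, np.random.default_rng(11))
        delta = np.abs(ex.volume - base_hu.astype(np.float32)) > 1e-3
        for organ in TARGET_ORGANS:
            organ_changed = delta[mask == MASK_LABELS[organ]].any()
            assert organ_changed == bool(ex.truth_labels[organ])

    def test_contrast_monotonicity_on_noise_free_volumes(self):
        diffs = []
        for contrast in (20.0, 40.0, 80.0):
            prev = {o: {c: 0.0 for c in ORGAN_CATEGORIES[o]} for o in TARGET_ORGANS}
            prev["liver"]["mass"] = 1.0
            cfg = ph.desk_scale_config(
                lesion_prevalence=prev, noise_sigma_hu=0.0, lesion_contrast_hu=contrast
            )
            base_hu, mask = ph.base_arrays(cfg)
            ex = ph.generate_exam(cfg, np.random.default_rng(2))
            organ = mask == MASK_LABELS["liver"]
            delta = np.abs(ex.volume - base_hu.astype(np.float32))[organ]
            diffs.append(delta[delta > 1e-3].mean())
        assert diffs[0] < diffs[1] < diffs[2]

    def test_masks_disjoint_and_connected(self):
        from scipy import ndimage

        _, mask = ph.base_arrays(ph.desk_scale_config())
        for organ, label in MASK_LABELS.items():
            organ_mask = mask == label
            if not organ_mask.any():
                continue
            _, n_components = ndimage.label(organ_mask)
            assert n_components == 1, organ


class TestReportRendering:
    def test_noise_free_round_trip_single_finding(self, lexicon):
        truth = {o: set() for o in TARGET_ORGANS}
        truth["liver"] = {"mass"}
        text, stated = ph.render_report(truth, 0.0, lexicon)
        assert stated == truth
        liver_sentences = [s for s in text.split(". ") if "liver" in s]
        assert len(liver_sentences) == 1
        assert "is seen" in liver_sentences[0]  # grade-4 phrase

    def test_all_normal_report_uses_grade_zero_phrases(self, lexicon):
        truth = {o: set() for o in TARGET_ORGANS}
        text, _ = ph.render_report(truth, 0.0, lexicon)
        sentences = [s for s in text.split(".") if s.strip()]
        assert len(sentences) == len(TARGET_ORGANS)
        assert all("no evidence of" in s.lower() for s in sentences)

    def test_rendered_reports_parse_back_to_truth(self, small_exam_batch, lexicon):
        _, exams = small_exam_batch
        for ex in exams:
            vecs = extract_organ_labels(ex.report_text, lexicon)
            parsed = {
                o: {c for c, v in vecs[o].categories.items() if v}
                for o in TARGET_ORGANS
            }
            assert parsed == {o: set(ex.truth_labels[o]) for o in TARGET_ORGANS}

    def test_noise_calibration(self):
        # empirical corruption rate over many organ statements ~ Binomial(p)
        rate = 0.3
        rng = np.random.default_rng(0)
        truth = {o: set() for o in TARGET_ORGANS}
        truth["liver"] = {"mass"}
        n, corrupted = 0, 0
        for _ in range(1700):  # ~10,200 organ statements
            stated = ph.corrupt_labels(truth, rate, rng)
            for o in TARGET_ORGANS:
                n += 1
                corrupted += stated[o] != truth[o]
        assert corrupted / n == pytest.approx(rate, abs=0.01)

    def test_corruption_always_changes_statement(self):
        rng = np.random.default_rng(1)
        truth = {"liver": {"mass"}, "spleen": set()}
        stated = ph.corrupt_labels(truth, 1.0, rng)
        assert stated["liver"] != truth["liver"]
        assert stated["spleen"] != truth["spleen"]


class TestGenerateCohort:
    def test_zero_exams(self, tmp_path):
        cfg = ph.desk_scale_config()
        manifest = ph.generate_cohort(cfg, 0, tmp_path / "c0")
        assert manifest["exams"] == []
        assert not list((tmp_path / "c0" / "volumes").glob("*"))

    def test_file_counts(self, tmp_path):
        cfg = ph.desk_scale_config()
        ph.generate_cohort(cfg, 7, tmp_path / "c7")
        assert len(list((tmp_path / "c7" / "volumes").glob("*.nii.gz"))) == 7
        assert len(list((tmp_path / "c7" / "masks").glob("*.nii.gz"))) == 7
        assert sum(1 for _ in open(tmp_path / "c7" / "reports.jsonl")) == 7

    def test_rerun_byte_identical_labels(self, tmp_path):
        cfg = ph.desk_scale_config(seed=9)
        m1 = ph.generate_cohort(cfg, 6, tmp_path / "a")
        m2 = ph.generate_cohort(cfg, 6, tmp_path / "b")
        assert m1["labels_sha256"] == m2["labels_sha256"]
        va = (tmp_path / "a" / "volumes" / "exam_00003.nii.gz").read_bytes()
        vb = (tmp_path / "b" / "volumes" / "exam_00003.nii.gz").read_bytes()
        assert va == vb

    def test_multiple_exams_per_patient(self, tmp_path):
        cfg = ph.desk_scale_config()
        manifest = ph.generate_cohort(cfg, 17, tmp_path / "c")
        patients = [e["patient_id"] for e in manifest["exams"]]
        assert len(set(patients)) < len(patients)

    def test_nifti_round_trip(self, tmp_path):
        import nibabel as nib

        cfg = ph.desk_scale_config()
        manifest = ph.generate_cohort(cfg, 1, tmp_path / "c1")
        img = nib.load(str(tmp_path / "c1" / manifest["exams"][0]["volume"]))
        assert img.shape == cfg.grid_shape
        assert np.allclose(np.diag(img.affine)[:3], cfg.spacing_mm)
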