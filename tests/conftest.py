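"""Shared fixtures: tiny synthetic configurations and on-disk archives."""

import pytest

from faersig import synthetic_faers as sf


@pytest.fixture
def tiny_config():
    """Small vocabulary, high rates: dense tables at a few dozen reports."""

    def make(seed=0, n_reports=60, signal_spec=None, duplicate_rate=0.1):
        drugs = [
            sf.DrugSpec("drug_a", 0.4, {"drug_a": 0.6, "DRUG A BRAND": 0.4}),
            sf.DrugSpec("drug_b", 0.35, {"drug_b": 1.0}),
            sf.DrugSpec("drug_c", 0.25, {"drug_c": 1.0}),
        ]
        pts = [
            sf.PtSpec("headache", "nervous system disorders", 0.5),
            sf.PtSpec("nausea", "gastrointestinal disorders", 0.4),
            sf.PtSpec("rash", "skin and subcutaneous tissue disorders", 0.3),
            sf.PtSpec("dizziness", "nervous system disorders", 0.3),
            sf.PtSpec("fatigue", "general disorders and administration site conditions", 0.25),
            sf.PtSpec("insomnia", "psychiatric disorders", 0.2),
            sf.PtSpec("tremor", "nervous system disorders", 0.15),
            sf.PtSpec("pericarditis", "cardiac disorders", 0.05),
        ]
        cfg = sf.SimConfig(seed=seed, n_reports=n_reports, drugs=drugs, pts=pts,
                           signal_spec=signal_spec or {},
                           duplicate_rate=duplicate_rate,
                           quarters=[(2023, 1), (2023, 2)])
        sf.validate(cfg)
        return cfg

    return make


@pytest.fixture
def tiny_archive(tmp_path, tiny_config):
    """A tiny generated quarterly archive on disk, with its maps."""
    cfg = tiny_config(seed=11, n_reports=50)
    result = sf.generate(cfg, out_dir=tmp_path / "archive")
    syn_path, soc_path = sf.write_maps(cfg, tmp_path / "archive")
    return {"config": cfg, "result": result, "dir": tmp_path / "archive",
            "synonyms": syn_path, "pt_soc": soc_path}
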