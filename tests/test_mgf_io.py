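"""mgf parsing/writing, catalog splits, and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specphenonet.mgf_io import (CLASS_LABELS, DatasetCatalog, MGFParseError,
                                 PROTEOMIC, SpectraFile, Spectrum,
                                 assign_splits, read_mgf, split_counts,
                                 write_mgf)

from .conftest import make_file, make_spectrum


# ---------------------------------------------------------------------------
# reading and writing

def test_empty_file_roundtrip(tmp_path):
    sf = SpectraFile("empty", PROTEOMIC, [])
    path = write_mgf(sf, tmp_path / "e.mgf")
    back = read_mgf(path)
    assert back.spectra == []
    assert "BEGIN IONS" not in path.read_text()


def test_two_blocks_rt_order(tmp_path):
    text = (
        "BEGIN IONS\nTITLE=b\nPEPMASS=500.0\nRTINSECONDS=2.0\n"
        "100.0 1.0\nEND IONS\n"
        "BEGIN IONS\nTITLE=a\nPEPMASS=400.0\nRTINSECONDS=1.0\n"
        "200.0 2.0\nEND IONS\n"
    )
    p = tmp_path / "two.mgf"
    p.write_text(text)
    sf = read_mgf(p)
    assert [s.rt_seconds for s in sf.spectra] == [1.0, 2.0]
    assert [s.title for s in sf.spectra] == ["a", "b"]


def test_single_peak_block_written_once(tmp_path):
    sf = SpectraFile("one", PROTEOMIC, [make_spectrum(1.0, [150.0], [3.0])])
    path = write_mgf(sf, tmp_path / "one.mgf")
    lines = path.read_text().splitlines()
    peak_lines = [l for l in lines
                  if l and l[0].isdigit() and "=" not in l]
    assert len(peak_lines) == 1


def test_missing_end_ions_names_line(tmp_path):
    p = tmp_path / "bad.mgf"
    p.write_text("BEGIN IONS\nTITLE=x\nRTINSECONDS=1\n100 1\n")
    with pytest.raises(MGFParseError, match="line 1"):
        read_mgf(p)


def test_missing_rt_is_an_error(tmp_path):
    p = tmp_path / "nort.mgf"
    p.write_text("BEGIN IONS\nTITLE=x\nPEPMASS=500\n100 1\nEND IONS\n")
    with pytest.raises(MGFParseError, match="retention time"):
        read_mgf(p)


def test_rt_fallback_from_title(tmp_path):
    p = tmp_path / "title.mgf"
    p.write_text("BEGIN IONS\nTITLE=scan 5 RT=42.5\nPEPMASS=500\n100 1\nEND IONS\n")
    sf = read_mgf(p)
    assert sf.spectra[0].rt_seconds == 42.5


def test_minutes_dialect_converts_small_values(tmp_path):
    p = tmp_path / "min.mgf"
    p.write_text("BEGIN IONS\nTITLE=x\nPEPMASS=500\nRTINSECONDS=2.5\n100 1\nEND IONS\n")
    assert read_mgf(p, rt_unit="minutes").spectra[0].rt_seconds == 150.0
    assert read_mgf(p, rt_unit="seconds").spectra[0].rt_seconds == 2.5


def test_peaks_resorted_by_mz():
    s = Spectrum("x", 500.0, 1.0, np.array([300.0, 100.0]), np.array([1.0, 2.0]))
    assert list(s.mz) == [100.0, 300.0]
    assert list(s.intensity) == [2.0, 1.0]


@settings(max_examples=100, deadline=None)
@given(st.data())
def test_roundtrip_identity(tmp_path_factory, data):
    """write_mgf then read_mgf reproduces RT, precursor and peaks exactly."""
    rng = np.random.default_rng(data.draw(st.integers(0, 2 ** 31 - 1)))
    n = data.draw(st.integers(0, 8))
    spectra = []
    for i in range(n):
        k = int(rng.integers(0, 6))
        spectra.append(make_spectrum(
            rt=float(rng.uniform(0, 1e4)),
            mz=np.sort(rng.uniform(50, 2000, k)),
            intensity=rng.lognormal(0, 2, k),
            precursor=float(rng.uniform(50, 2000)),
        ))
    sf = SpectraFile("rt", PROTEOMIC, spectra)
    path = tmp_path_factory.mktemp("mgf") / "r.mgf"
    back = read_mgf(write_mgf(sf, path))
    assert len(back) == len(sf)
    for a, b in zip(sf.spectra, back.spectra):
        assert b.rt_seconds == a.rt_seconds
        assert abs(b.precursor_mz - a.precursor_mz) <= 1e-6 * max(a.precursor_mz, 1)
        np.testing.assert_array_equal(a.mz, b.mz)
        np.testing.assert_array_equal(a.intensity, b.intensity)


def test_roundtrip_100_spectra(tmp_path):
    sf = make_file(100, seed=3)
    back = read_mgf(write_mgf(sf, tmp_path / "big.mgf"))
    assert len(back) == 100
    for a, b in zip(sf.spectra, back.spectra):
        np.testing.assert_array_equal(a.mz, b.mz)


# ---------------------------------------------------------------------------
# catalog and splits

def _catalog(per_class):
    cat = DatasetCatalog()
    for label in CLASS_LABELS:
        for i in range(per_class):
            cat.add(f"{label}{i:03d}", PROTEOMIC, label)
    return cat


def test_split_300_files_is_180_120():
    cat = assign_splits(_catalog(75), train_fraction=0.6, seed=0)
    counts = split_counts(cat)
    assert counts["train"] == 180
    assert counts["test"] == 120


def test_split_stratified_per_class():
    cat = assign_splits(_catalog(75), train_fraction=0.6, seed=4)
    per = cat.entries.groupby(["label", "split"]).size()
    for label in CLASS_LABELS:
        assert per[(label, "train")] == 45
        assert per[(label, "test")] == 30


def test_split_ten_files_single_fraction():
    cat = DatasetCatalog()
    for i in range(10):
        cat.add(f"a{i}", PROTEOMIC, "CNT")
    for i in range(10):
        cat.add(f"b{i}", PROTEOMIC, "OVC")
    for i in range(10):
        cat.add(f"c{i}", PROTEOMIC, "RNC")
    for i in range(10):
        cat.add(f"d{i}", PROTEOMIC, "PRC")
    out = assign_splits(cat, train_fraction=0.6, seed=1)
    per = out.entries.groupby(["label", "split"]).size()
    assert per[("CNT", "train")] == 6 and per[("CNT", "test")] == 4


def test_split_deterministic_given_seed():
    a = assign_splits(_catalog(20), seed=9).entries
    b = assign_splits(_catalog(20), seed=9).entries
    assert (a.split == b.split).all()
    c = assign_splits(_catalog(20), seed=10).entries
    assert (a.split != c.split).any()


def test_split_groups_both_layers_of_a_subject():
    cat = DatasetCatalog()
    for label in CLASS_LABELS:
        for i in range(5):
            cat.add(f"{label}{i}", "proteomic", label)
            cat.add(f"{label}{i}", "metabolomic", label)
    out = assign_splits(cat, seed=2)
    per_file = out.entries.groupby("file_id").split.nunique()
    assert (per_file == 1).all()


def test_augmented_entries_inherit_source_split():
    cat = _catalog(10)
    cat.add("CNT000_aug0", PROTEOMIC, "CNT", provenance="augmented",
            source_file_id="CNT000")
    out = assign_splits(cat, seed=3)
    src = out.entries.loc[out.entries.file_id == "CNT000", "split"].iloc[0]
    aug = out.entries.loc[out.entries.file_id == "CNT000_aug0", "split"].iloc[0]
    assert aug == src


def test_split_errors_on_tiny_class():
    cat = DatasetCatalog()
    cat.add("x", PROTEOMIC, "CNT")
    with pytest.raises(ValueError, match="CNT"):
        assign_splits(cat, seed=0)


def test_catalog_csv_roundtrip(tmp_path):
    cat = _catalog(3)
    cat.add("CNT000_aug0", PROTEOMIC, "CNT", provenance="augmented",
            source_file_id="CNT000")
    path = cat.save_csv(tmp_path / "cat.csv")
    back = DatasetCatalog.load_csv(path)
    assert len(back) == len(cat)
    assert back.entries.iloc[-1].source_file_id == "CNT000"
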