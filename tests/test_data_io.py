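"""Count-matrix I/O, validation, and preprocessing contracts."""

import numpy as np
import pytest

import zipo
from zipo.exceptions import ValidationError


def test_dense_read_library_sizes(tmp_path):
    p = tmp_path / "counts.tsv"
    p.write_text("\tg1\tg2\nc1\t0\t1\nc2\t2\t0\nc3\t5\t3\n")
    cm = zipo.read_counts(p)
    assert list(cm.library_sizes()) == [1, 2, 8]
    assert cm.cell_ids == ["c1", "c2", "c3"]
    assert cm.gene_ids == ["g1", "g2"]


def test_comma_dialect_sniffed(tmp_path):
    p = tmp_path / "counts.csv"
    p.write_text(",g1,g2\nc1,1,2\n")
    cm = zipo.read_counts(p)
    assert cm.values.tolist() == [[1, 2]]


@pytest.mark.parametrize("fmt,orientation", [
    ("mtx", "genes-as-rows"),
    ("mtx", "cells-as-rows"),
    ("dense-delimited", "cells-as-rows"),
])
def test_round_trip_identity(tmp_path, rng, fmt, orientation):
    values = rng.poisson(0.3, size=(50, 100))
    values[:, 0] += 1  # no zero-library cells
    cm = zipo.CountMatrix(
        values,
        [f"c{i}" for i in range(50)],
        [f"g{j}" for j in range(100)],
    )
    path = tmp_path / ("m.mtx" if fmt == "mtx" else "m.tsv")
    zipo.write_counts(cm, path, format=fmt, orientation=orientation)
    back = zipo.read_counts(path, format=fmt, orientation=orientation)
    assert np.array_equal(back.values, cm.values)
    assert back.cell_ids == cm.cell_ids
    assert back.gene_ids == cm.gene_ids


def test_empty_mtx_all_zero_library_errors(tmp_path):
    path = tmp_path / "empty.mtx"
    path.write_text(
        "%%MatrixMarket matrix coordinate integer general\n5 4 1\n1 1 0\n"
    )
    (tmp_path / "empty.mtx.rownames.txt").write_text(
        "\n".join(f"g{i}" for i in range(5)) + "\n")
    (tmp_path / "empty.mtx.colnames.txt").write_text(
        "\n".join(f"c{i}" for i in range(4)) + "\n")
    with pytest.raises(ValidationError, match="zero library size"):
        zipo.read_counts(path)


def test_partial_zero_cells_dropped_with_warning(tmp_path):
    p = tmp_path / "counts.tsv"
    p.write_text("\tg1\tg2\nc1\t0\t0\nc2\t2\t1\n")
    with pytest.warns(UserWarning, match="zero library size"):
        cm = zipo.read_counts(p)
    assert cm.cell_ids == ["c2"]


def test_missing_file_and_missing_companions(tmp_path):
    with pytest.raises(FileNotFoundError):
        zipo.read_counts(tmp_path / "nope.tsv")
    path = tmp_path / "m.mtx"
    path.write_text("%%MatrixMarket matrix coordinate integer general\n1 1 1\n1 1 2\n")
    with pytest.raises(FileNotFoundError, match="companion"):
        zipo.read_counts(path)


@pytest.mark.parametrize("bad,msg", [
    ("\tg1\tg2\nc1\t-1\t2\n", "negative count at cell 'c1', gene 'g1'"),
    ("\tg1\tg2\nc1\t1\t2.5\n", "non-integer count at cell 'c1', gene 'g2'"),
])
def test_invalid_entries_name_first_offender(tmp_path, bad, msg):
    p = tmp_path / "bad.tsv"
    p.write_text(bad)
    with pytest.raises(ValidationError) as exc:
        zipo.read_counts(p)
    assert msg in str(exc.value)


def test_duplicate_identifiers_rejected():
    with pytest.raises(ValidationError, match="duplicate cell identifiers"):
        zipo.CountMatrix(np.ones((2, 1), int), ["a", "a"], ["g"])
    with pytest.raises(ValidationError, match="duplicate gene identifiers"):
        zipo.CountMatrix(np.ones((1, 2), int), ["a"], ["g", "g"])


# -- preprocessing -------------------------------------------------------------


def _cm(rows):
    arr = np.asarray(rows)
    return zipo.CountMatrix(
        arr, [f"c{i}" for i in range(arr.shape[0])],
        [f"g{j}" for j in range(arr.shape[1])],
    )


def test_preprocess_library_normalize():
    out = zipo.preprocess(_cm([[2, 2, 4]]), zipo.PreprocessSpec(library_normalize=True))
    assert np.allclose(out, [[0.25, 0.25, 0.5]])


def test_preprocess_log_transform():
    out = zipo.preprocess(_cm([[0, 0, 2]]), zipo.PreprocessSpec(log_transform=True))
    assert np.allclose(out, np.log1p([[0, 0, 2]]))
    # log(1 + x) maps a count of e-1 to exactly 1
    cm_float = zipo.CountMatrix(np.array([[0, 0, 1]]), ["c0"], ["g0", "g1", "g2"])
    assert np.allclose(
        zipo.preprocess(cm_float, zipo.PreprocessSpec(log_transform=True)),
        [[0, 0, np.log(2.0)]],
    )


def test_preprocess_composition_normalize_then_log():
    out = zipo.preprocess(_cm([[1, 3]]),
                          zipo.PreprocessSpec(log_transform=True,
                                              library_normalize=True))
    assert np.allclose(out, [[np.log(1.25), np.log(1.75)]])


def test_preprocess_identity_when_flags_off(rng):
    cm = _cm(rng.poisson(2.0, size=(5, 4)) + 1)
    out = zipo.preprocess(cm, zipo.PreprocessSpec())
    assert out.dtype == np.float64
    assert np.array_equal(out, cm.values.astype(float))


def test_preprocess_zero_row_errors_under_normalization():
    cm = zipo.CountMatrix(np.array([[0, 0], [1, 2]]), ["c0", "c1"], ["g0", "g1"])
    with pytest.raises(ValidationError, match="zero library size"):
        zipo.preprocess(cm, zipo.PreprocessSpec(library_normalize=True))


# -- denoised export -----------------------------------------------------------


def _dist(log_l, log_mu_rows):
    log_mu = np.log(np.asarray(log_mu_rows, dtype=float))
    r = np.zeros_like(log_mu)
    return zipo.CellDistribution(log_l=np.asarray(log_l, float), r=r, log_mu=log_mu)


def test_export_denoised_rates_and_row_sums(tmp_path, rng):
    import pandas as pd

    cm = _cm([[1, 2], [3, 4]])
    dist = _dist(np.log([100.0, 10.0]), [[0.1, 0.9], [0.5, 0.5]])
    path = tmp_path / "den.tsv"
    zipo.export_denoised(cm, dist, path)
    m = pd.read_csv(path, sep="\t", index_col=0)
    assert np.allclose(m.to_numpy()[0], [10.0, 90.0])
    # mu rows sum to 1 => output rows sum to predicted library sizes
    assert np.allclose(m.to_numpy().sum(axis=1), [100.0, 10.0])
    z = pd.read_csv(tmp_path / "den.zeroprob.tsv", sep="\t", index_col=0)
    assert np.allclose(z.to_numpy(), 0.5)


def test_export_denoised_matches_direct_product(tmp_path, rng):
    import pandas as pd

    n, g = 7, 5
    raw = rng.dirichlet(np.ones(g), size=n)
    log_l = rng.normal(2, 1, n)
    cm = _cm(rng.poisson(1.0, size=(n, g)) + 1)
    dist = zipo.CellDistribution(log_l=log_l, r=np.zeros((n, g)),
                                 log_mu=np.log(raw))
    path = tmp_path / "den.tsv"
    zipo.export_denoised(cm, dist, path)
    m = pd.read_csv(path, sep="\t", index_col=0).to_numpy()
    expected = np.exp(log_l)[:, None] * raw
    assert np.allclose(m, expected, rtol=1e-12, atol=0)


def test_export_denoised_dimension_mismatch(tmp_path):
    cm = _cm([[1, 2, 3]])
    dist = _dist([0.0], [[0.5, 0.5]])
    with pytest.raises(ValidationError, match="does not match"):
        zipo.export_denoised(cm, dist, tmp_path / "x.tsv")
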