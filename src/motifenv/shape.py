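"""Pentamer-based propeller-twist profiling of aligned pools.

Propeller twist (degrees, typically negative) is a base-pair structural
parameter that tracks DNA flexibility; it is predicted per position by
looking up the pentamer centered there in an externally supplied table
(e.g. a DNAshape-derived table).  Being a base-pair parameter, the
value of a pentamer equals the value of its reverse complement.

For testing and simulation, :func:`synthetic_table` builds an
RC-symmetric table whose values rise affinely with pentamer GC count
(GC-rich DNA has less pronounced propeller twist) plus seeded noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import seqcodec
from .scan import AlignedPool

_POW4 = 4 ** np.arange(4, -1, -1)


class ShapeTableError(ValueError):
    pass


def _pentamer_index(codes5: np.ndarray) -> int:
    return int(np.dot(codes5, _POW4))


def _index_to_pentamer(idx: int) -> str:
    out = []
    for p in _POW4:
        out.append(seqcodec.ALPHABET[(idx // p) % 4])
    return "".join(out)


def _rc_index(idx: int) -> int:
    codes = np.array([(idx // p) % 4 for p in _POW4], dtype=np.uint8)
    return _pentamer_index(seqcodec.revcomp_codes(codes))


class ShapeTable:
    """Pentamer -> propeller twist lookup, stored as a dense 1024 array."""

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (1024,):
            raise ShapeTableError("shape table must cover all 1024 pentamers")
        if np.any(np.isnan(values)):
            missing = [_index_to_pentamer(i) for i in np.nonzero(np.isnan(values))[0]]
            raise ShapeTableError(f"missing pentamers: {', '.join(missing[:5])}")
        bad = [
            _index_to_pentamer(i)
            for i in range(1024)
            if abs(values[i] - values[_rc_index(i)]) > 1e-6
        ]
        if bad:
            raise ShapeTableError(
                f"table not reverse-complement symmetric at: {', '.join(bad[:5])}"
            )
        self.values = values

    def __getitem__(self, pentamer: str) -> float:
        return float(self.values[_pentamer_index(seqcodec.encode(pentamer))])

    @property
    def vmin(self) -> float:
        return float(self.values.min())

    @property
    def vmax(self) -> float:
        return float(self.values.max())

    def to_tsv(self, path, reduced: bool = False) -> None:
        """Write pentamer/value rows; ``reduced`` keeps one row per
        reverse-complement pair (the canonical, lexicographically
        smaller member)."""
        with open(path, "w") as fh:
            fh.write("pentamer\tpropeller_twist\n")
            for i in range(1024):
                if reduced and _rc_index(i) < i:
                    continue
                fh.write(f"{_index_to_pentamer(i)}\t{self.values[i]:.4f}\n")


def load_shape_table(path) -> ShapeTable:
    """Load a pentamer TSV (512 reduced or 1024 full rows).

    For a reduced table the reverse-complement entries are synthesized;
    duplicate rows with conflicting values are an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ShapeTableError("expected two columns: pentamer, value")
    values = np.full(1024, np.nan)
    conflicts = []
    for pent, val in zip(df.iloc[:, 0], df.iloc[:, 1]):
        pent = str(pent).upper()
        codes = seqcodec.encode(pent)
        if codes.size != 5 or np.any(codes >= 4):
            raise ShapeTableError(f"invalid pentamer {pent!r}")
        for idx in {_pentamer_index(codes), _rc_index(_pentamer_index(codes))}:
            if not np.isnan(values[idx]) and abs(values[idx] - float(val)) > 1e-6:
                conflicts.append(_index_to_pentamer(idx))
            values[idx] = float(val)
    if conflicts:
        raise ShapeTableError(
            f"asymmetric duplicate entries for: {', '.join(sorted(set(conflicts))[:5])}"
        )
    if np.any(np.isnan(values)):
        missing = [_index_to_pentamer(i) for i in np.nonzero(np.isnan(values))[0]]
        raise ShapeTableError(f"missing pentamers: {', '.join(missing[:5])}")
    return ShapeTable(values)


def synthetic_table(
    seed: int = 0,
    base: float = -11.0,
    gc_step: float = 1.1,
    noise_sd: float = 0.3,
) -> ShapeTable:
    """RC-symmetric synthetic propeller-twist table.

    value(p) = base + gc_step * GC_count(p) + noise, with the noise
    shared within each reverse-complement pair.  Mimics the empirical
    trend that GC-rich pentamers have less negative propeller twist;
    intended for tests and simulations, not as a physical model.
    """
    rng = np.random.default_rng(seed)
    values = np.full(1024, np.nan)
    for i in range(1024):
        j = _rc_index(i)
        if not np.isnan(values[i]):
            continue
        codes = np.array([(i // p) % 4 for p in _POW4])
        gc = int(np.sum((codes == 1) | (codes == 2)))
        v = base + gc_step * gc + rng.normal(0.0, noise_sd)
        values[i] = values[j] = v
    return ShapeTable(values)


def propeller_profile(seq: str | np.ndarray, table: ShapeTable) -> np.ndarray:
    """Per-position propeller twist of one sequence.

    Position i takes the value of the pentamer seq[i-2 .. i+2]; the
    first and last two positions, and any position whose pentamer
    contains an undefined base, are NaN.
    """
    codes = seqcodec.encode(seq) if isinstance(seq, str) else np.asarray(seq)
    return _profile_matrix(np.atleast_2d(codes), table)[0]


def _profile_matrix(codes: np.ndarray, table: ShapeTable) -> np.ndarray:
    n, slen = codes.shape
    out = np.full((n, slen), np.nan)
    if slen < 5:
        return out
    idx = np.zeros((n, slen - 4), dtype=np.int64)
    bad = np.zeros((n, slen - 4), dtype=bool)
    for j, p in enumerate(_POW4):
        sub = codes[:, j : j + slen - 4]
        bad |= sub >= 4
        idx += p * np.minimum(sub, 3).astype(np.int64)
    vals = table.values[idx]
    vals[bad] = np.nan
    out[:, 2 : slen - 2] = vals
    return out


def pool_profile_matrix(
    pool: AlignedPool, table: ShapeTable
) -> tuple[np.ndarray, np.ndarray]:
    """Propeller-twist values at the pool's flank positions
    ([n x P] with NaN where undefined, plus relative positions)."""
    cols, positions = pool.flank_columns()
    full = _profile_matrix(pool.codes, table)
    vals = full[:, cols]
    if pool.mask is not None:
        vals = np.where(pool.mask[:, cols], np.nan, vals)
    return vals, positions


def compare_shape(
    pool_b: AlignedPool,
    pool_u: AlignedPool,
    table: ShapeTable,
    test: str = "rank_sum",
    fdr_method: str = "storey",
    min_n: int = 10,
):
    """Positional bound-vs-unbound comparison of propeller twist."""
    from .envstats import delta_profile_from_matrices

    mat_b, pos_b = pool_profile_matrix(pool_b, table)
    mat_u, pos_u = pool_profile_matrix(pool_u, table)
    if pos_b.size != pos_u.size or np.any(pos_b != pos_u):
        raise ValueError("pools have incompatible alignment frames")
    return delta_profile_from_matrices(
        mat_b, mat_u, pos_b, "propeller_twist",
        test=test, fdr_method=fdr_method, min_n=min_n,
    )
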