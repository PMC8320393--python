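"""Three-level definitive screening designs (DSDs).

A DSD for ``k`` factors consists of ``2k + 1`` runs: the rows of a
conference matrix ``C`` of order ``k``, their element-wise negations
(fold-over pairs), and one overall center run.  The conference-matrix
structure (zero diagonal, off-diagonal entries ±1, ``CᵀC = (k − 1)·I``)
guarantees that main effects are orthogonal to every quadratic and
two-factor-interaction column — the property that lets a single screening
block estimate main effects, curvature and interactions at once.

Conference matrices are built by the Paley construction when
``k − 1`` is an odd prime, with a small verified lookup table covering the
remaining even orders up to 16.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "default_factor_specs",
    "build_conference_matrix",
    "generate_dsd",
    "assemble_block",
    "assemble_study",
    "validate_design",
    "DesignDiagnostics",
    "write_design",
    "read_design",
    "factor_columns",
]

REFERENCE_RUN_ID = "ref"

# Orders without a prime-Paley construction.  Row strings use '+', '-', '0'.
# Order 10 is the Paley matrix over GF(9); order 16 comes from doubling the
# order-8 skew Paley matrix as [[C, C+I], [C-I, -C]].  Both satisfy
# CᵀC = (k-1)·I, which the test suite re-checks.
_CONFERENCE_TABLE: dict[int, list[str]] = {
    10: [
        "0+++++++++",
        "+0+++--+--",
        "++0+-+--+-",
        "+++0--+--+",
        "++--0+++--",
        "+-+-+0+-+-",
        "+--+++0--+",
        "++--+--0++",
        "+-+--+-+0+",
        "+--+--+++0",
    ],
    16: [
        "0+++++++++++++++",
        "-0--+-++-+--+-++",
        "-+0--+-+-++--+-+",
        "-++0--+--+++--+-",
        "--++0--+--+++--+",
        "-+-++0---+-+++--",
        "--+-++0---+-+++-",
        "---+-++0---+-+++",
        "-+++++++0-------",
        "----+-+++0++-+--",
        "-+---+-++-0++-+-",
        "-++---+-+--0++-+",
        "--++---+++--0++-",
        "-+-++---+-+--0++",
        "--+-++--++-+--0+",
        "---+-++-+++-+--0",
    ],
}


@dataclass(frozen=True)
class FactorSpec:
    """One screened media component with optional real-unit levels."""

    factor_id: str
    name: str = ""
    low: float | None = None
    mid: float | None = None
    high: float | None = None
    unit: str = ""

    def __post_init__(self) -> None:
        if self.low is not None and self.mid is not None and self.high is not None:
            if not (self.low < self.mid < self.high):
                raise ValueError(
                    f"{self.factor_id}: real-unit levels must satisfy low < mid < high"
                )


def default_factor_specs(k: int = 12) -> list[FactorSpec]:
    """Coded factor labels ``c01 … c{k}`` without real-unit concentrations."""
    return [FactorSpec(factor_id=f"c{i + 1:02d}") for i in range(k)]


def _is_prime(n: int) -> bool:
    if n < 2:
        return False
    for p in range(2, int(n**0.5) + 1):
        if n % p == 0:
            return False
    return True


def _paley_conference(q: int) -> np.ndarray:
    """Paley conference matrix of order q + 1 for an odd prime q."""
    chi = np.zeros(q, dtype=int)
    residues = {pow(a, 2, q) for a in range(1, q)}
    for a in range(1, q):
        chi[a] = 1 if a in residues else -1
    Q = np.empty((q, q), dtype=int)
    for a in range(q):
        for b in range(q):
            Q[a, b] = chi[(a - b) % q]
    C = np.zeros((q + 1, q + 1), dtype=int)
    C[0, 1:] = 1
    C[1:, 1:] = Q
    # q ≡ 1 (mod 4): symmetric type; q ≡ 3 (mod 4): skew type.
    C[1:, 0] = 1 if q % 4 == 1 else -1
    return C


def _from_table(k: int) -> np.ndarray:
    rows = _CONFERENCE_TABLE[k]
    lut = {"0": 0, "+": 1, "-": -1}
    return np.array([[lut[ch] for ch in row] for row in rows], dtype=int)


def build_conference_matrix(k: int) -> np.ndarray:
    """Conference matrix of even order ``k`` with ``CᵀC = (k − 1)·I``.

    Raises
    ------
    ValueError
        If ``k`` is odd, below 4, or no construction is available.
    """
    if k % 2 != 0 or k < 4:
        raise ValueError(f"conference matrices require even order >= 4, got k={k}")
    if k in _CONFERENCE_TABLE:
        C = _from_table(k)
    elif _is_prime(k - 1):
        C = _paley_conference(k - 1)
    else:
        raise ValueError(f"no conference-matrix construction available for k={k}")
    gram = C.T @ C
    if not np.array_equal(gram, (k - 1) * np.eye(k, dtype=int)):
        raise AssertionError(f"conference matrix of order {k} failed the Gram check")
    return C


def factor_columns(design: pd.DataFrame) -> list[str]:
    """The coded factor columns of a design table, in stored order."""
    meta = {"run_id", "run_role", "block_id"}
    return [c for c in design.columns if c not in meta]


def generate_dsd(
    k: int,
    factor_specs: list[FactorSpec] | None = None,
    seed: int | None = None,
    randomize: bool = False,
) -> pd.DataFrame:
    """Generate a 2k + 1-run definitive screening design.

    Rows are the conference matrix, its negation, and the center run, with
    fold-over pairs adjacent (rows 2i−1 and 2i negate each other).  With
    ``randomize=True`` the run order is shuffled with ``seed``; run
    identities (``run_id``) follow the formulation, not the position.
    """
    if factor_specs is None:
        factor_specs = default_factor_specs(k)
    if len(factor_specs) != k:
        raise ValueError(f"expected {k} factor specs, got {len(factor_specs)}")
    ids = [f.factor_id for f in factor_specs]
    if len(set(ids)) != k:
        raise ValueError("factor_id values must be unique")

    C = build_conference_matrix(k)
    rows = np.empty((2 * k + 1, k), dtype=int)
    rows[0:2 * k:2] = C
    rows[1:2 * k:2] = -C
    rows[2 * k] = 0

    design = pd.DataFrame(rows, columns=ids)
    design.insert(0, "run_id", [f"r{i + 1:02d}" for i in range(2 * k + 1)])
    design.insert(1, "run_role", "dsd_formulation")
    if randomize:
        rng = np.random.default_rng(seed)
        design = design.iloc[rng.permutation(len(design))].reset_index(drop=True)
    return design


def assemble_block(
    design: pd.DataFrame,
    block_id: str,
    include_reference: bool = True,
    seed: int | None = None,
    randomize: bool = False,
) -> pd.DataFrame:
    """Stamp a block (donor) id on a design and append the reference run.

    The reference medium sits outside the coded ±1 component space, so its
    coded levels are recorded as NA and it never enters model features.
    """
    block = design.copy()
    if randomize:
        rng = np.random.default_rng(seed)
        block = block.iloc[rng.permutation(len(block))].reset_index(drop=True)
    if include_reference:
        ref = {c: np.nan for c in factor_columns(design)}
        ref.update(run_id=REFERENCE_RUN_ID, run_role="reference")
        block = pd.concat([block, pd.DataFrame([ref])], ignore_index=True)
    block["block_id"] = block_id
    return block


def assemble_study(
    design: pd.DataFrame,
    block_ids: list[str],
    include_reference: bool = True,
    seed: int | None = None,
    randomize: bool = True,
) -> pd.DataFrame:
    """Stack one randomized complete block per donor."""
    seeds = np.random.SeedSequence(seed).generate_state(len(block_ids)) % (2**31)
    blocks = [
        assemble_block(design, bid, include_reference, seed=int(s), randomize=randomize)
        for bid, s in zip(block_ids, seeds)
    ]
    return pd.concat(blocks, ignore_index=True)


@dataclass
class DesignDiagnostics:
    """Report of the structural checks that make a design a valid DSD."""

    n_dsd_runs: int
    fold_over_closed: bool
    has_single_center_run: bool
    zeros_per_column: dict[str, int]
    column_sums: dict[str, int]
    max_main_quad_dot: float
    max_main_interaction_dot: float
    messages: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.messages


def validate_design(design: pd.DataFrame) -> DesignDiagnostics:
    """Check fold-over pairing, zero counts and main-effect aliasing.

    Cross products are computed over dsd rows in exact integer arithmetic;
    a genuine DSD gives ``Xᵀmain · Xquad = 0`` and ``Xᵀmain · Xint = 0``.
    """
    cols = factor_columns(design)
    dsd = design[design.get("run_role", "dsd_formulation") == "dsd_formulation"]
    X = dsd[cols].to_numpy(dtype=int)
    n, k = X.shape
    messages: list[str] = []

    if not np.isin(X, (-1, 0, 1)).all():
        messages.append("coded levels outside {-1, 0, +1}")
    if n != 2 * k + 1:
        messages.append(f"expected {2 * k + 1} dsd rows for k={k}, found {n}")

    row_set = {tuple(r) for r in X}
    fold_over = all(tuple(-np.array(r)) in row_set for r in row_set)
    if not fold_over:
        messages.append("dsd rows are not closed under negation")
    n_center = int((X == 0).all(axis=1).sum())
    if n_center != 1:
        messages.append(f"expected exactly one center run, found {n_center}")

    zeros = {c: int((X[:, j] == 0).sum()) for j, c in enumerate(cols)}
    sums = {c: int(X[:, j].sum()) for j, c in enumerate(cols)}
    bad_zero = [c for c, z in zeros.items() if z != 3]
    if bad_zero:
        messages.append(f"columns without exactly 3 zeros: {bad_zero}")
    if any(s != 0 for s in sums.values()):
        messages.append("factor columns do not sum to zero")

    quad = X**2
    inter = np.stack(
        [X[:, i] * X[:, j] for i in range(k) for j in range(i + 1, k)], axis=1
    ) if k >= 2 else np.empty((n, 0), dtype=int)
    mq = np.abs(X.T @ quad)
    mi = np.abs(X.T @ inter) if inter.size else np.zeros((k, 0))
    max_mq = int(mq.max()) if mq.size else 0
    max_mi = int(mi.max()) if mi.size else 0
    if max_mq != 0:
        messages.append("main effects aliased with quadratic terms")
    if max_mi != 0:
        messages.append("main effects aliased with two-factor interactions")

    return DesignDiagnostics(
        n_dsd_runs=n,
        fold_over_closed=fold_over,
        has_single_center_run=n_center == 1,
        zeros_per_column=zeros,
        column_sums=sums,
        max_main_quad_dot=float(max_mq),
        max_main_interaction_dot=float(max_mi),
        messages=messages,
    )


def _format_level(v) -> str:
    if pd.isna(v):
        return ""
    f = float(v)
    return str(int(f)) if f.is_integer() else repr(f)


def write_design(design: pd.DataFrame, path) -> None:
    """Write a design CSV; reference rows get empty level cells.

    Integer coded levels print as -1/0/1; continuous levels (cluster-media
    and other derived formulations) keep full precision.
    """
    out = design.copy()
    for c in factor_columns(out):
        out[c] = out[c].map(_format_level)
    out.to_csv(path, index=False)


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path)
    for c in factor_columns(design):
        design[c] = pd.to_numeric(design[c], errors="coerce")
    return design
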