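"""Reading, writing and validating bipartite interaction networks.

Incidence matrices follow the web-of-life.es labelled-CSV dialect: the
first row holds column-species names, the first column row-species names,
and cells hold interaction records. Any strictly positive cell is treated
as an interaction (the analysis is binary); blanks count as absence.

Rows are guild A (plants / hosts), columns guild B (animals / parasites);
every downstream convention is fixed to that orientation.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from envnet.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

INTERACTION_CLASSES = ("antagonistic", "mutualistic")

#: Name of the environmental covariate the pipeline conditions on, by default
#: the standard deviation of the annual temperature fluctuation in °C.
DEFAULT_ENV_VAR = "temperature_variability"


@dataclass
class InteractionNetwork:
    """A binary bipartite interaction network with metadata.

    Parameters
    ----------
    id : str
        Unique identifier within a :class:`NetworkSet`.
    incidence : ndarray of shape (m, n)
        Binary matrix; ``incidence[i, j] == 1`` when row-guild species *i*
        interacts with column-guild species *j*.
    row_names, col_names : list of str
        Species names; lengths must match the matrix dimensions.
    interaction_class : str or None
        ``"antagonistic"`` or ``"mutualistic"``.
    sub_class : str or None
        Free-form sub-class such as ``"plant-pollinator"``.
    latitude, longitude : float or None
        Sampling location in decimal degrees.
    env : dict
        Environmental covariates by name (e.g. ``temperature_variability``
        in °C).
    """

    id: str
    incidence: np.ndarray
    row_names: list[str] | None = None
    col_names: list[str] | None = None
    interaction_class: str | None = None
    sub_class: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    env: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        B = np.asarray(self.incidence)
        if B.ndim != 2 or B.size == 0:
            raise ValidationError(f"{self.id}: incidence must be a non-empty 2-D matrix")
        if not np.isin(B, (0, 1)).all():
            raise ValidationError(f"{self.id}: incidence entries must be 0 or 1")
        if B.sum() == 0:
            raise ValidationError(f"{self.id}: incidence has no interactions")
        self.incidence = B.astype(np.int8)
        m, n = B.shape
        if self.row_names is None:
            self.row_names = [f"R{i}" for i in range(m)]
        if self.col_names is None:
            self.col_names = [f"C{j}" for j in range(n)]
        if len(self.row_names) != m or len(self.col_names) != n:
            raise ValidationError(f"{self.id}: name lists do not match matrix shape")
        if self.interaction_class is not None:
            self.interaction_class = normalize_class(self.interaction_class)

    @property
    def shape(self) -> tuple[int, int]:
        return self.incidence.shape

    def environment(self, variable: str = DEFAULT_ENV_VAR) -> float:
        try:
            return self.env[variable]
        except KeyError:
            raise ValidationError(f"{self.id}: missing environment variable {variable!r}")


@dataclass
class NetworkSet:
    """An ordered collection of networks with unique ids."""

    networks: list[InteractionNetwork]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.networks:
            raise ValidationError("NetworkSet must be non-empty")
        ids = [net.id for net in self.networks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate network ids: {dupes}")

    def __iter__(self):
        return iter(self.networks)

    def __len__(self) -> int:
        return len(self.networks)

    @property
    def ids(self) -> list[str]:
        return [net.id for net in self.networks]

    def metadata_frame(self, env_vars: tuple[str, ...] | None = None) -> pd.DataFrame:
        """Tabulate per-network metadata (one row per network, id-indexed)."""
        if env_vars is None:
            names: set[str] = set()
            for net in self.networks:
                names.update(net.env)
            env_vars = tuple(sorted(names))
        rows = []
        for net in self.networks:
            row: dict[str, object] = {
                "id": net.id,
                "interaction_class": net.interaction_class,
                "sub_class": net.sub_class,
                "latitude": net.latitude,
                "longitude": net.longitude,
            }
            for v in env_vars:
                row[v] = net.env.get(v, np.nan)
            rows.append(row)
        return pd.DataFrame(rows).set_index("id")


def normalize_class(value: str) -> str:
    v = str(value).strip().lower()
    if v not in INTERACTION_CLASSES:
        raise ValidationError(
            f"interaction_class must be one of {INTERACTION_CLASSES}, got {value!r}"
        )
    return v


def binarize(matrix: np.ndarray) -> np.ndarray:
    """Map strictly positive cells to 1, others to 0. Idempotent."""
    M = np.asarray(matrix, dtype=float)
    if (M < 0).any():
        raise FormatError("negative cell value in incidence matrix")
    return (M > 0).astype(np.int8)


def read_incidence_csv(path, dialect: str = "labeled"):
    """Read an incidence matrix CSV.

    Parameters
    ----------
    path : path-like
    dialect : {"labeled", "bare"}
        ``labeled``: first row = column species names, first column = row
        species names (web-of-life.es layout). ``bare``: numbers only.

    Returns
    -------
    (matrix, row_names, col_names)
        ``matrix`` is binary int8; weighted records are binarized at > 0.
    """
    if dialect not in ("labeled", "bare"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        if dialect == "labeled":
            df = pd.read_csv(path, index_col=0, header=0)
            row_names = [str(x) for x in df.index]
            col_names = [str(x) for x in df.columns]
        else:
            df = pd.read_csv(path, header=None)
            row_names = [f"R{i}" for i in range(df.shape[0])]
            col_names = [f"C{j}" for j in range(df.shape[1])]
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        n_blank = int(np.isnan(values).sum())
        logger.warning("%s: %d blank/non-numeric cells treated as 0", path, n_blank)
        warnings.warn(f"{path}: {n_blank} blank cells treated as absence", stacklevel=2)
        values = np.nan_to_num(values, nan=0.0)
    matrix = binarize(values)
    if matrix.sum() == 0:
        raise ValidationError(f"{path}: all-zero incidence matrix")
    return matrix, row_names, col_names


def write_incidence_csv(path, matrix: np.ndarray, row_names=None, col_names=None) -> None:
    """Write a matrix in the labeled dialect (round-trips with the reader)."""
    M = np.asarray(matrix)
    m, n = M.shape
    row_names = row_names if row_names is not None else [f"R{i}" for i in range(m)]
    col_names = col_names if col_names is not None else [f"C{j}" for j in range(n)]
    pd.DataFrame(M, index=row_names, columns=col_names).to_csv(path)


_META_REQUIRED = ("id", "interaction_class", "sub_class")
_META_KNOWN = _META_REQUIRED + ("latitude", "longitude")


def read_metadata(path) -> pd.DataFrame:
    """Read the per-network metadata table, keyed by network id.

    Columns are matched case-insensitively. ``interaction_class`` values are
    normalized to the two-level enum; extra columns are kept verbatim and
    interpreted as environmental variables downstream.
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in _META_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required metadata column {col!r}")
    df["id"] = df["id"].astype(str)
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise ValidationError(f"{path}: duplicate metadata ids {dupes}")
    df["interaction_class"] = df["interaction_class"].map(normalize_class)
    return df.set_index("id")


def prune_isolated(network: InteractionNetwork) -> InteractionNetwork:
    """Drop all-zero rows and columns (zero-degree species).

    Isolated species carry no eigenvector weight in λ1/λ2 but break the
    unit-diagonal normalization of the competition-overlap matrix, so they
    are removed before metric computation. No-op when nothing is isolated.
    """
    B = network.incidence
    keep_r = B.sum(axis=1) > 0
    keep_c = B.sum(axis=0) > 0
    if keep_r.all() and keep_c.all():
        return network
    if not keep_r.any() or not keep_c.any():
        raise ValidationError(f"{network.id}: pruning would empty the matrix")
    return replace(
        network,
        incidence=B[np.ix_(keep_r, keep_c)],
        row_names=[n for n, k in zip(network.row_names, keep_r) if k],
        col_names=[n for n, k in zip(network.col_names, keep_c) if k],
    )


def screen_collinearity(env_table: pd.DataFrame, threshold: float = 0.7):
    """Flag pairs of environmental variables with |Pearson r| above threshold.

    Strongly correlated bioclimatic variables make multi-covariate models
    uninterpretable (multicollinearity), which is why the pipeline defaults
    to a single environmental covariate. Constant columns are excluded with
    a warning (their correlation is undefined).

    Returns
    -------
    list of (name_a, name_b, r)
        Unordered pairs with ``|r| > threshold``, sorted lexicographically;
        ``r`` keeps its sign.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    df = env_table.select_dtypes(include=[np.number])
    if len(df) < 3:
        raise ValidationError("need at least 3 rows to screen collinearity")
    keep = []
    for col in df.columns:
        if np.isclose(df[col].std(ddof=1), 0.0):
            warnings.warn(f"constant column {col!r} excluded from screen", stacklevel=2)
        else:
            keep.append(col)
    flagged = []
    for a, b in itertools.combinations(sorted(keep), 2):
        r = float(np.corrcoef(df[a], df[b])[0, 1])
        if abs(r) > threshold:
            flagged.append((a, b, r))
    return flagged


def write_network_set(directory, network_set: NetworkSet, env_vars=None) -> None:
    """Write one incidence CSV per network plus a ``metadata.csv`` table."""
    import os

    os.makedirs(directory, exist_ok=True)
    for net in network_set:
        write_incidence_csv(
            os.path.join(directory, f"{net.id}.csv"),
            net.incidence,
            net.row_names,
            net.col_names,
        )
    meta = network_set.metadata_frame(env_vars)
    meta.to_csv(os.path.join(directory, "metadata.csv"))


def read_network_set(directory, require_class: bool = True) -> NetworkSet:
    """Read a directory of incidence CSVs with a ``metadata.csv`` table."""
    import os

    meta_path = os.path.join(directory, "metadata.csv")
    meta = read_metadata(meta_path)
    env_cols = [c for c in meta.columns if c not in _META_KNOWN]
    networks = []
    for net_id, row in meta.iterrows():
        mpath = os.path.join(directory, f"{net_id}.csv")
        if not os.path.exists(mpath):
            warnings.warn(f"metadata id {net_id!r} has no matrix file; skipped", stacklevel=2)
            continue
        matrix, row_names, col_names = read_incidence_csv(mpath)
        env = {c: float(row[c]) for c in env_cols if pd.notna(row[c])}
        networks.append(
            InteractionNetwork(
                id=str(net_id),
                incidence=matrix,
                row_names=row_names,
                col_names=col_names,
                interaction_class=row["interaction_class"] if require_class else None,
                sub_class=row.get("sub_class"),
                latitude=_opt_float(row.get("latitude")),
                longitude=_opt_float(row.get("longitude")),
                env=env,
            )
        )
    return NetworkSet(networks, provenance=str(directory))


def _opt_float(x):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else float(x)
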