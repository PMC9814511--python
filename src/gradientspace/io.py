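"""Domain types and tabular I/O for parcellated fMRI gradient analysis.

All on-disk artifacts are UTF-8, tab-separated text with ``.`` as the
decimal separator, so fixtures are bit-stable across platforms.  Internal
parcel indices are 0-based; external tables always carry explicit parcel
names so no off-by-one is ever user-visible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    ParseError,
    SchemaError,
    ValidationError,
)

#: Canonical seven-network vocabulary (functional resting-state networks).
NETWORKS = ("VIS", "SMN", "DAN", "VAN", "LIM", "FPN", "DMN")

# Per-network parcel counts of the canonical 400-area / 7-network cortical
# parcellation; used to size the bundled synthetic stand-in scheme.
_NETWORK_SIZES = {
    "VIS": 61,
    "SMN": 77,
    "DAN": 46,
    "VAN": 47,
    "LIM": 26,
    "FPN": 52,
    "DMN": 91,
}

_NETWORK_ABBREV = {
    "VIS": "Vis",
    "SMN": "SomMot",
    "DAN": "DorsAttn",
    "VAN": "SalVentAttn",
    "LIM": "Limbic",
    "FPN": "Cont",
    "DMN": "Default",
}


@dataclass(frozen=True)
class ParcellationScheme:
    """Assignment of cortical parcels to functional networks.

    Parameters
    ----------
    parcel_names
        One name per parcel, unique.
    networks
        One label per parcel, drawn from :data:`NETWORKS`.
    hemispheres
        One of ``{"L", "R", "NA"}`` per parcel.
    """

    parcel_names: tuple[str, ...]
    networks: tuple[str, ...]
    hemispheres: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.parcel_names)
        if len(self.networks) != n or len(self.hemispheres) != n:
            raise SchemaError("parcel_names, networks and hemispheres must have equal length")
        if len(set(self.parcel_names)) != n:
            raise SchemaError("parcel names must be unique")
        bad = sorted(set(self.networks) - set(NETWORKS))
        if bad:
            raise SchemaError(f"unknown network labels: {bad}; expected one of {NETWORKS}")
        bad_h = sorted(set(self.hemispheres) - {"L", "R", "NA"})
        if bad_h:
            raise SchemaError(f"unknown hemisphere labels: {bad_h}")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_names)

    @property
    def present_networks(self) -> tuple[str, ...]:
        present = set(self.networks)
        return tuple(n for n in NETWORKS if n in present)

    def indices_of(self, network: str) -> np.ndarray:
        """0-based parcel indices belonging to ``network``."""
        if network not in NETWORKS:
            raise ValidationError(f"unknown network {network!r}")
        return np.flatnonzero(np.asarray(self.networks) == network)

    def network_indicator(self) -> dict[str, np.ndarray]:
        return {net: self.indices_of(net) for net in self.present_networks}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel_id": np.arange(self.n_parcels),
                "parcel_name": self.parcel_names,
                "network": self.networks,
                "hemisphere": self.hemispheres,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ParcellationScheme":
        # keep_default_na: hemisphere "NA" is a label, not a missing value
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"parcel_id", "parcel_name", "network", "hemisphere"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"parcel metadata file is missing columns: {sorted(missing)}")
        df = df.sort_values("parcel_id", key=lambda s: s.astype(int))
        return cls(
            parcel_names=tuple(df["parcel_name"]),
            networks=tuple(df["network"]),
            hemispheres=tuple(df["hemisphere"]),
        )


def default_scheme() -> ParcellationScheme:
    """The bundled 400-parcel, 7-network scheme.

    This is a synthetic stand-in that reproduces the network sizes and
    naming convention of the canonical 400-area cortical parcellation; it
    is NOT the real atlas lookup table, which users may substitute via
    :meth:`ParcellationScheme.from_tsv`.
    """
    names: list[str] = []
    networks: list[str] = []
    hemis: list[str] = []
    for hemi in ("L", "R"):
        for net in NETWORKS:
            size = _NETWORK_SIZES[net]
            n_side = (size + 1) // 2 if hemi == "L" else size // 2
            # keep the total at exactly 400
            if net == "DMN" and hemi == "L":
                n_side = size // 2
            elif net == "DMN" and hemi == "R":
                n_side = (size + 1) // 2
            for i in range(1, n_side + 1):
                names.append(f"7Networks_{hemi}H_{_NETWORK_ABBREV[net]}_{i}")
                networks.append(net)
                hemis.append(hemi)
    return ParcellationScheme(tuple(names), tuple(networks), tuple(hemis))


def small_scheme(n_parcels: int = 70, seed: int | None = None) -> ParcellationScheme:
    """A reduced scheme with the same 7 networks, sizes proportional to the
    400-parcel default.  Intended for fast simulation studies."""
    if n_parcels < len(NETWORKS):
        raise ValidationError("need at least one parcel per network")
    raw = {net: _NETWORK_SIZES[net] * n_parcels / 400.0 for net in NETWORKS}
    sizes = {net: max(1, int(np.floor(v))) for net, v in raw.items()}
    # distribute the remainder by largest fractional part
    rem = n_parcels - sum(sizes.values())
    order = sorted(NETWORKS, key=lambda n: raw[n] - np.floor(raw[n]), reverse=True)
    for net in (order * 2)[: max(rem, 0)]:
        sizes[net] += 1
    while sum(sizes.values()) > n_parcels:
        big = max(NETWORKS, key=lambda n: sizes[n])
        sizes[big] -= 1
    names, networks, hemis = [], [], []
    for net in NETWORKS:
        for i in range(1, sizes[net] + 1):
            names.append(f"Synth_{_NETWORK_ABBREV[net]}_{i}")
            networks.append(net)
            hemis.append("NA")
    return ParcellationScheme(tuple(names), tuple(networks), tuple(hemis))


@dataclass
class ParcelTimeSeries:
    """A time x parcels signal matrix for one scan.

    ``censor_mask`` marks retained volumes (``True`` = kept).  Values at
    censored frames are undefined downstream of preprocessing and are set
    to NaN there.
    """

    data: np.ndarray
    tr_seconds: float
    censor_mask: np.ndarray = None  # type: ignore[assignment]
    subject_id: str = ""
    condition_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValidationError("time series must be a T x P matrix with T >= 2")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        if self.censor_mask is None:
            self.censor_mask = np.ones(self.data.shape[0], dtype=bool)
        self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
        if self.censor_mask.shape != (self.data.shape[0],):
            raise ValidationError("censor_mask length must equal the number of volumes")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    @property
    def retained(self) -> np.ndarray:
        """Data restricted to retained (uncensored) volumes."""
        return self.data[self.censor_mask]


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters per volume.

    Translations are in mm; rotations are taken as already converted to
    mm-equivalent arc length (see the preprocessing CLI flag for degree
    inputs), so the frame-wise Euclidean norm of derivatives is in mm.
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise SchemaError("motion trace must have exactly 6 columns")


@dataclass
class RunConfig:
    """Analysis settings; the defaults reproduce the main-analysis choices
    (90% row sparsity, diffusion operator anisotropy 0.5, automatic
    diffusion-time damping, 0.4 mm FD censoring with the previous frame,
    0.01-0.1 Hz passband, global signal regression on, squared network
    distances, 8 co-activation patterns, 3 gradients for geometry)."""

    sparsity: float = 0.9
    alpha: float = 0.5
    diffusion_time: float = 0.0
    n_components: int = 10
    n_gradients_for_geometry: int = 3
    fd_threshold_mm: float = 0.4
    passband_hz: tuple[float, float] = (0.01, 0.1)
    gsr: bool = True
    eccentricity_squared: bool = True
    cap_k: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.passband_hz
        if not 0 <= lo < hi:
            raise ValidationError(f"passband must satisfy 0 <= low < high, got {self.passband_hz}")
        if not 0 <= self.sparsity < 1:
            raise ValidationError(f"sparsity must be in [0, 1), got {self.sparsity}")
        if not 0 <= self.alpha <= 1:
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.diffusion_time < 0:
            raise ValidationError("diffusion_time must be non-negative")
        if self.n_components < 1 or self.n_gradients_for_geometry < 1:
            raise ValidationError("component counts must be positive")
        if self.fd_threshold_mm <= 0:
            raise ValidationError("fd_threshold_mm must be positive")
        if self.cap_k < 2:
            raise ValidationError("cap_k must be at least 2")


_BOOL_KEYS = {"gsr", "eccentricity_squared"}
_INT_KEYS = {"n_components", "n_gradients_for_geometry", "cap_k", "rng_seed"}
_FLOAT_KEYS = {"sparsity", "alpha", "diffusion_time", "fd_threshold_mm"}


def load_config(path: str | Path) -> RunConfig:
    """Read a flat ``key=value`` text document into a :class:`RunConfig`.

    Unspecified keys take the package defaults.  Lines starting with ``#``
    and blank lines are ignored.
    """
    known = {f.name for f in dataclasses.fields(RunConfig)}
    values: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigurationError(f"line {lineno}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in known:
            raise ConfigurationError(f"unknown configuration key {key!r}")
        try:
            if key in _BOOL_KEYS:
                if value.lower() not in {"true", "false", "0", "1"}:
                    raise ValueError
                values[key] = value.lower() in {"true", "1"}
            elif key in _INT_KEYS:
                values[key] = int(value)
            elif key in _FLOAT_KEYS:
                values[key] = float(value)
            elif key == "passband_hz":
                lo, hi = (float(v) for v in value.split(","))
                values[key] = (lo, hi)
            else:  # pragma: no cover - future keys
                values[key] = value
        except ValueError as exc:
            raise ConfigurationError(f"cannot parse value for {key!r}: {value!r}") from exc
    return RunConfig(**values)  # type: ignore[arg-type]


def write_config(config: RunConfig, path: str | Path) -> None:
    lines = []
    for f in dataclasses.fields(RunConfig):
        v = getattr(config, f.name)
        if f.name == "passband_hz":
            v = f"{v[0]},{v[1]}"
        lines.append(f"{f.name}={v}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# time-series / motion / tidy-table I/O


def read_timeseries(
    path: str | Path,
    scheme: ParcellationScheme,
    tr_seconds: float = 2.0,
    subject_id: str = "",
    condition_id: str = "",
) -> ParcelTimeSeries:
    """Read a tab-separated time x parcels matrix.

    The first row must name the parcels; columns are reordered to the
    scheme's parcel order, so column permutations in the file are
    harmless.  Missing or extra parcel columns raise :class:`SchemaError`
    naming the offenders.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=0)
    except ValueError as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc
    file_cols = list(df.columns)
    want = list(scheme.parcel_names)
    missing = sorted(set(want) - set(file_cols))
    extra = sorted(set(file_cols) - set(want))
    if missing or extra:
        raise SchemaError(
            f"{path}: parcel columns do not match the scheme; "
            f"missing={missing[:5]}{'...' if len(missing) > 5 else ''} "
            f"extra={extra[:5]}{'...' if len(extra) > 5 else ''}"
        )
    df = df[want]
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col].apply(lambda v: not _is_number(v))
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"{path}: non-numeric value in column {col!r} at data row {row}")
    return ParcelTimeSeries(
        data=df.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
        subject_id=subject_id,
        condition_id=condition_id,
    )


def _is_number(v: object) -> bool:
    try:
        float(v)  # type: ignore[arg-type]
        return True
    except (TypeError, ValueError):
        return False


def write_timeseries(ts: ParcelTimeSeries, scheme: ParcellationScheme, path: str | Path) -> None:
    if ts.n_parcels != scheme.n_parcels:
        raise SchemaError("time series parcel count does not match the scheme")
    df = pd.DataFrame(ts.data, columns=list(scheme.parcel_names))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_motion(path: str | Path) -> MotionTrace:
    """Read a 6-column, headerless motion-parameter file."""
    arr = np.loadtxt(path, ndmin=2)
    return MotionTrace(arr)


def write_motion(motion: MotionTrace, path: str | Path) -> None:
    np.savetxt(path, motion.params, fmt="%.17g", delimiter="\t")


def write_table(records: Sequence[Mapping[str, object]], path: str | Path) -> None:
    """Write tidy records to a TSV with a header; values survive a
    read-back to 12 significant digits."""
    records = list(records)
    if records:
        fields = list(records[0].keys())
        for i, rec in enumerate(records):
            if list(rec.keys()) != fields:
                raise SchemaError(f"record {i} has fields {list(rec.keys())}, expected {fields}")
        df = pd.DataFrame.from_records(records, columns=fields)
    else:
        df = pd.DataFrame()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default), encoding="utf-8")


def _json_default(o: object):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if dataclasses.is_dataclass(o) and not isinstance(o, type):
        return dataclasses.asdict(o)
    raise TypeError(f"cannot serialize {type(o)!r}")
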