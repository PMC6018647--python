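"""Reading, validation and alignment of the five tabular inputs.

All tables are UTF-8 CSV with the first column holding row identifiers
(plots or species) and the header row holding column identifiers
(species, metabolite codes, trait names or soil variables).
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "OccurrenceMatrix",
    "BinaryTraitMatrix",
    "ContinuousTraitMatrix",
    "EnvironmentTable",
    "AnalysisBundle",
    "load_bundle",
    "write_bundle",
    "restrict_to_trait_coverage",
]

COORD_COLUMNS = ("longitude", "latitude")
TEXTURE_COLUMNS = ("sand", "silt", "clay")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _read_csv_checked(path: str | Path, what: str) -> pd.DataFrame:
    """Read a CSV, rejecting duplicate row or column identifiers.

    pandas mangles duplicate column names on read, so the header is
    inspected directly.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh))
    columns = header[1:]
    dupes = {c for c in columns if columns.count(c) > 1}
    if dupes:
        raise ValidationError(
            f"{what} table {path.name}: duplicate column identifier(s) {sorted(dupes)}"
        )
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dup = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(
            f"{what} table {path.name}: duplicate row identifier(s) {dup}"
        )
    return df


def _check_binary(df: pd.DataFrame, what: str) -> pd.DataFrame:
    values = df.to_numpy()
    bad = ~np.isin(values, (0, 1)) | ~np.isfinite(values.astype(float))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"{what}: non-binary cell value {df.iat[r, c]!r} at "
            f"row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    return df.astype(int)


@dataclass
class OccurrenceMatrix:
    """Plot x species presence/absence matrix.

    ``flagged_plots`` lists plots that fail the >=2-species requirement
    for within-plot tests; they are flagged, never silently dropped.
    """

    data: pd.DataFrame
    flagged_plots: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = _check_binary(self.data, "occurrence")
        richness = self.data.sum(axis=1)
        self.flagged_plots = sorted(set(self.flagged_plots) | set(richness.index[richness < 2]))

    @property
    def plot_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.columns)

    def usable_plots(self) -> list[str]:
        return [p for p in self.plot_ids if p not in self.flagged_plots]

    def plot_species(self, plot_id: str) -> list[str]:
        row = self.data.loc[plot_id]
        return list(row.index[row == 1])


@dataclass
class BinaryTraitMatrix:
    """Species x binary-trait (metabolite presence/absence) matrix."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = _check_binary(self.data, "binary trait matrix")

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ContinuousTraitMatrix:
    """Species x continuous-trait matrix; rows are complete by construction."""

    data: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValidationError(
                "continuous trait matrix holds missing values; drop incomplete "
                "species rows before constructing the matrix"
            )
        self.data = self.data.astype(float)
        if self.standardized:
            mu = self.data.mean(axis=0).to_numpy()
            sd = self.data.std(axis=0, ddof=1).to_numpy()
            if not (np.all(np.abs(mu) < 1e-9) and np.all(np.abs(sd - 1) < 1e-9)):
                raise ValidationError("standardized flag set but columns are not z-scored")

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class EnvironmentTable:
    """Per-plot soil variables plus decimal-degree coordinates."""

    data: pd.DataFrame  # soil variables only
    coordinates: pd.DataFrame  # columns longitude, latitude

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if list(self.coordinates.columns) != list(COORD_COLUMNS):
            raise ValidationError(
                f"coordinates must have columns {COORD_COLUMNS}, got "
                f"{list(self.coordinates.columns)}"
            )
        lon = self.coordinates["longitude"]
        lat = self.coordinates["latitude"]
        if ((lon < -180) | (lon > 180)).any() or ((lat < -90) | (lat > 90)).any():
            raise ValidationError("coordinates outside valid decimal-degree ranges")
        for col in TEXTURE_COLUMNS:
            if col in self.data.columns:
                v = self.data[col]
                if ((v < 0) | (v > 100)).any():
                    raise ValidationError(f"texture percentage {col!r} outside [0, 100]")
        if not self.data.index.equals(self.coordinates.index):
            raise ValidationError("environment table and coordinates disagree on plots")

    @property
    def plot_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variable_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class AnalysisBundle:
    occurrence: OccurrenceMatrix
    sm: BinaryTraitMatrix
    rut: ContinuousTraitMatrix
    env: EnvironmentTable
    coverage: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        occ_species = set(self.occurrence.species_ids)
        for name, mat in (("SM", self.sm), ("RUT", self.rut)):
            extra = sorted(set(mat.species_ids) - occ_species)
            if extra:
                raise ValidationError(
                    f"{name} table names species absent from the occurrence matrix: {extra}"
                )
        if list(self.env.plot_ids) != list(self.occurrence.plot_ids):
            raise ValidationError("environment table plots do not match occurrence plots")
        if not self.coverage:
            self.coverage = coverage_report(self)


def coverage_report(bundle: AnalysisBundle) -> dict:
    """Species/plot coverage arithmetic on identifier sets."""
    sm_species = set(bundle.sm.species_ids)
    rut_species = set(bundle.rut.species_ids)
    both = sm_species & rut_species
    occ = bundle.occurrence
    plots_with_both = [
        p for p in occ.plot_ids if any(s in both for s in occ.plot_species(p))
    ]

    def _usable(covered: set[str]) -> list[str]:
        sub = occ.data[[s for s in occ.species_ids if s in covered]]
        richness = sub.sum(axis=1)
        return list(richness.index[richness >= 2])

    return {
        "n_plots": len(occ.plot_ids),
        "n_species": len(occ.species_ids),
        "n_sm_species": len(sm_species),
        "n_rut_species": len(rut_species),
        "n_species_with_both": len(both),
        "species_with_both": sorted(both),
        "n_plots_with_dual_covered_species": len(plots_with_both),
        "plots_usable_sm": _usable(sm_species),
        "plots_usable_rut": _usable(rut_species),
        "flagged_plots": list(occ.flagged_plots),
    }


def load_bundle(
    occurrence_path: str | Path,
    sm_path: str | Path,
    rut_path: str | Path,
    env_path: str | Path,
) -> AnalysisBundle:
    """Load, validate and align the four CSV inputs into one bundle.

    The environment table carries the plot coordinates in columns named
    ``longitude`` and ``latitude``; the remaining columns are soil
    variables.  Species rows with any missing continuous-trait value are
    excluded from the continuous matrix (recorded in the coverage
    report), matching an analysis restricted to fully characterized
    species.
    """
    occ = OccurrenceMatrix(_read_csv_checked(occurrence_path, "occurrence"))
    sm = BinaryTraitMatrix(_read_csv_checked(sm_path, "SM"))

    rut_raw = _read_csv_checked(rut_path, "RUT")
    incomplete = list(rut_raw.index[rut_raw.isna().any(axis=1)])
    if incomplete:
        warnings.warn(
            f"dropping {len(incomplete)} species with incomplete continuous traits: "
            f"{incomplete}",
            stacklevel=2,
        )
    rut = ContinuousTraitMatrix(rut_raw.drop(index=incomplete))

    env_raw = _read_csv_checked(env_path, "environment")
    missing = [c for c in COORD_COLUMNS if c not in env_raw.columns]
    if missing:
        raise ValidationError(f"environment table lacks coordinate column(s) {missing}")
    coords = env_raw[list(COORD_COLUMNS)].astype(float)
    soil = env_raw.drop(columns=list(COORD_COLUMNS))
    env = EnvironmentTable(soil, coords)

    bundle = AnalysisBundle(occ, sm, rut, env)
    if incomplete:
        bundle.coverage["rut_species_dropped_incomplete"] = incomplete
    return bundle


def write_bundle(bundle: AnalysisBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle back to the CSV dialect `load_bundle` reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "occurrence": out / "occurrence.csv",
        "sm": out / "sm.csv",
        "rut": out / "rut.csv",
        "env": out / "environment.csv",
    }
    bundle.occurrence.data.to_csv(paths["occurrence"], index_label="plot")
    bundle.sm.data.to_csv(paths["sm"], index_label="species")
    bundle.rut.data.to_csv(paths["rut"], index_label="species")
    env_out = pd.concat([bundle.env.coordinates, bundle.env.data], axis=1)
    env_out.to_csv(paths["env"], index_label="plot")
    (out / "coverage.json").write_text(json.dumps(bundle.coverage, indent=2))
    return paths


def restrict_to_trait_coverage(
    bundle: AnalysisBundle, trait_set: str | list[str]
) -> OccurrenceMatrix:
    """Occurrence matrix restricted to species covered by a trait set.

    ``trait_set`` is ``"SM"``, ``"RUT"`` or an explicit list of
    continuous-trait ids (a trait subset, which restricts to species with
    complete data for those traits — with no imputation this equals the
    full RUT species set).  Plots left with fewer than two covered
    species are flagged, not dropped.
    """
    if isinstance(trait_set, str):
        key = trait_set.upper()
        if key == "SM":
            covered = set(bundle.sm.species_ids)
        elif key == "RUT":
            covered = set(bundle.rut.species_ids)
        else:
            raise ValidationError(f"unknown trait set {trait_set!r}")
    else:
        unknown = sorted(set(trait_set) - set(bundle.rut.trait_ids))
        if unknown:
            raise ValidationError(f"unknown continuous trait id(s) {unknown}")
        covered = set(bundle.rut.species_ids)

    keep = [s for s in bundle.occurrence.species_ids if s in covered]
    sub = bundle.occurrence.data[keep]
    richness = sub.sum(axis=1)
    flagged = list(richness.index[richness < 2])
    if len(sub.index) - len(flagged) < 2:
        raise ValidationError(
            "restriction to trait coverage leaves fewer than two usable plots"
        )
    return OccurrenceMatrix(sub, flagged_plots=flagged)
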