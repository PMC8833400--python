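"""Cohort container, validation and CSV round-tripping.

A cohort bundles four patient-aligned tables: the radiomic feature matrix,
the acquisition batch table, the clinical covariates, and the survival
outcome.  Every table is a pandas DataFrame indexed by ``patient_id``; the
index order is shared across tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Cohort", "validate_cohort", "read_cohort", "CohortValidationError"]

CLINICAL_CONTINUOUS = ("age", "bmi", "pack_years")
CLINICAL_CATEGORICAL = ("sex", "race", "ecog")


class CohortValidationError(ValueError):
    """Raised when the cohort tables are inconsistent or malformed."""


@dataclass
class Cohort:
    """Patient-aligned feature / batch / clinical / survival tables.

    ``latent_phenotype`` carries the ground-truth cluster label and is only
    present for simulated cohorts; it is never consumed by analysis stages.
    """

    features: pd.DataFrame
    batches: pd.DataFrame
    clinical: pd.DataFrame
    survival: pd.DataFrame
    latent_phenotype: pd.Series | None = None

    @property
    def patient_ids(self) -> pd.Index:
        return self.features.index

    @property
    def n_patients(self) -> int:
        return len(self.features)

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write the cohort tables as CSV files with a `patient_id` column.

        The ground-truth latent phenotype, when present, goes to a separate
        file that no analysis stage reads.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = {}
        for name, table in [
            ("features", self.features),
            ("batches", self.batches),
            ("clinical", self.clinical),
            ("survival", self.survival),
        ]:
            path = outdir / f"{name}.csv"
            table.to_csv(path, index_label="patient_id")
            written[name] = str(path)
        if self.latent_phenotype is not None:
            path = outdir / "latent_phenotype.csv"
            self.latent_phenotype.rename("latent_phenotype").to_csv(
                path, index_label="patient_id"
            )
            written["latent_phenotype"] = str(path)
        return written


def _read_indexed(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise CohortValidationError(f"{path} lacks a 'patient_id' column")
    return df.set_index("patient_id")


def read_cohort(indir: str | Path) -> Cohort:
    """Load and validate a cohort written by :meth:`Cohort.write`."""
    indir = Path(indir)
    tables = {name: _read_indexed(indir / f"{name}.csv")
              for name in ("features", "batches", "clinical", "survival")}
    return validate_cohort(**tables)


def validate_cohort(
    features: pd.DataFrame,
    batches: pd.DataFrame,
    clinical: pd.DataFrame,
    survival: pd.DataFrame,
    latent_phenotype: pd.Series | None = None,
) -> Cohort:
    """Check table consistency and return a canonically ordered cohort.

    All tables must carry identical patient-id sets; rows are reordered to
    the feature table's order.  Feature cells must be numeric and finite;
    survival requires positive finite times and a 0/1 event indicator.
    """
    ids = features.index
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()
        raise CohortValidationError(f"duplicate patient ids: {dupes}")
    if len(ids) < 2:
        raise CohortValidationError("a cohort needs at least 2 patients")
    for name, table in [("batches", batches), ("clinical", clinical), ("survival", survival)]:
        missing = ids.difference(table.index)
        extra = table.index.difference(ids)
        if len(missing) or len(extra):
            raise CohortValidationError(
                f"{name} table patient ids do not match features: "
                f"missing={missing.tolist()} extra={extra.tolist()}"
            )

    feat = features.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(feat.to_numpy(dtype=float, na_value=np.nan))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise CohortValidationError(
            f"non-numeric or non-finite feature cell at "
            f"(patient {feat.index[r]!r}, feature {feat.columns[c]!r})"
        )
    if feat.columns.has_duplicates:
        raise CohortValidationError("duplicate feature names")

    batches = batches.loc[ids]
    if batches.isna().any().any():
        raise CohortValidationError("missing batch level(s)")
    clinical = clinical.loc[ids]
    survival = survival.loc[ids]
    for col in ("time", "event"):
        if col not in survival.columns:
            raise CohortValidationError(f"survival table lacks column {col!r}")
    time = pd.to_numeric(survival["time"], errors="coerce")
    event = pd.to_numeric(survival["event"], errors="coerce")
    if not np.isfinite(time).all() or (time <= 0).any():
        raise CohortValidationError("survival times must be finite and positive")
    if not event.isin([0, 1]).all():
        raise CohortValidationError("event indicator must be 0/1")
    survival = pd.DataFrame({"time": time.astype(float), "event": event.astype(int)},
                            index=ids)
    if latent_phenotype is not None:
        latent_phenotype = latent_phenotype.loc[ids]
    return Cohort(
        features=feat.astype(float),
        batches=batches,
        clinical=clinical,
        survival=survival,
        latent_phenotype=latent_phenotype,
    )
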