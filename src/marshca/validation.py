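"""Map-agreement statistics: confusion matrix, overall accuracy, Cohen's kappa.

Convention: the reference map indexes ROWS of the confusion matrix, the
comparison map indexes columns; cells where either map is nodata are
excluded.  Kappa is the chance-corrected agreement
``(p_o - p_e) / (1 - p_e)`` with the expected agreement ``p_e`` taken from
the row/column marginals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .raster_io import LandscapeGrid, check_compatible

__all__ = ["AgreementReport", "cross_tabulate", "transition_matrix_between"]


@dataclass
class AgreementReport:
    """Cross-tabulation of two maps over their jointly valid cells."""

    confusion: np.ndarray          # counts, reference rows x comparison cols
    class_codes: list[int]
    overall_accuracy: float
    kappa: float
    transition_areas: np.ndarray   # hectares, same layout
    n_cells: int

    def confusion_frame(self, names: dict[int, str] | None = None) -> pd.DataFrame:
        labels = [names.get(c, str(c)) if names else str(c) for c in self.class_codes]
        return pd.DataFrame(self.confusion, index=labels, columns=labels)

    def summary(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "kappa": self.kappa,
            "n_cells": self.n_cells,
        }

    def write(self, directory: str | Path, stem: str = "agreement",
              names: dict[int, str] | None = None) -> None:
        import json

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.confusion_frame(names).to_csv(directory / f"{stem}_confusion.csv")
        labels = [names.get(c, str(c)) if names else str(c) for c in self.class_codes]
        pd.DataFrame(self.transition_areas, index=labels, columns=labels).to_csv(
            directory / f"{stem}_transition_areas_ha.csv")
        (directory / f"{stem}_summary.json").write_text(
            json.dumps(self.summary(), indent=2))


def _kappa_from_confusion(confusion: np.ndarray) -> tuple[float, float]:
    total = confusion.sum()
    p_o = np.trace(confusion) / total
    marg_r = confusion.sum(axis=1) / total
    marg_c = confusion.sum(axis=0) / total
    p_e = float(marg_r @ marg_c)
    if p_e >= 1.0 - 1e-15:
        # both maps are constant: agreement is degenerate
        warnings.warn("degenerate marginals (p_e = 1); kappa set by convention")
        return float(p_o), 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return float(p_o), float((p_o - p_e) / (1.0 - p_e))


def cross_tabulate(reference: LandscapeGrid, comparison: LandscapeGrid) -> AgreementReport:
    """Confusion matrix, overall accuracy and kappa between two maps.

    Classes are the union of codes present in either map (scheme order).
    """
    check_compatible(reference, comparison)
    mask = reference.valid_mask() & comparison.valid_mask()
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no jointly valid cells")

    codes = [c for c in reference.scheme.codes
             if (reference.values[mask] == c).any() or (comparison.values[mask] == c).any()]
    lut = {c: i for i, c in enumerate(codes)}
    ri = np.vectorize(lut.get, otypes=[np.int64])(reference.values[mask])
    ci = np.vectorize(lut.get, otypes=[np.int64])(comparison.values[mask])
    confusion = np.zeros((len(codes), len(codes)), dtype=np.int64)
    np.add.at(confusion, (ri, ci), 1)

    p_o, kappa = _kappa_from_confusion(confusion)
    return AgreementReport(
        confusion=confusion,
        class_codes=codes,
        overall_accuracy=p_o,
        kappa=kappa,
        transition_areas=confusion * reference.cell_area_ha,
        n_cells=n,
    )


def transition_matrix_between(
    observed_a: LandscapeGrid, observed_b: LandscapeGrid
) -> pd.DataFrame:
    """Hectares moving i -> j between two dated maps (diagonal = persistence).

    Row sums equal the class areas at the first date, column sums at the
    second (over jointly valid cells) — exact bookkeeping of change.
    """
    report = cross_tabulate(observed_a, observed_b)
    labels = [observed_a.scheme.name_of(c) for c in report.class_codes]
    return pd.DataFrame(report.transition_areas, index=labels, columns=labels)
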