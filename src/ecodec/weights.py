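"""Aggregate fitted decoder weights into band x location contribution tables.

For every cross-validation fold and muscle, the absolute weights are averaged
over the lag axis, channels are mapped to their electrode-grid column
("location"; column #1 is nearest the central sulcus) and averaged within a
column, and the resulting (band, location) cells are normalised by the
per-muscle maximum so the largest cell of each (fold, muscle) is exactly 1.
The summary statistic per (band, location) is the median over muscles within
a fold, then the mean of those medians across folds.  The long-format export
is the input a 3-way ANOVA (band x location x muscle) would consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, ParameterError
from .session_io import ElectrodeLayout
from .slir import SlirModel


@dataclass
class WeightSummary:
    """Normalised weight contributions per (fold, muscle, band, location)."""

    table: pd.DataFrame  # columns: fold, muscle, band, location, value in [0, 1]
    band_names: list[str]
    locations: list[int]
    muscle_names: list[str]
    n_folds: int

    def band_location_means(self) -> pd.DataFrame:
        """Mean over folds of the median over muscles; bands x locations."""
        med = (self.table
               .groupby(["fold", "band", "location"], sort=False)["value"]
               .median().reset_index())
        out = (med.groupby(["band", "location"], sort=False)["value"].mean()
               .unstack("location"))
        return out.reindex(index=self.band_names, columns=self.locations)

    def band_totals(self) -> pd.Series:
        return (self.table.groupby("band", sort=False)["value"].sum()
                .reindex(self.band_names))

    def location_totals(self) -> pd.Series:
        return (self.table.groupby("location", sort=False)["value"].sum()
                .reindex(self.locations))


def aggregate_weights(models: list[SlirModel], layout: ElectrodeLayout,
                      signed: bool = False) -> WeightSummary:
    """Build the weight-contribution summary from per-fold fitted models.

    ``signed=False`` (default) averages \\|w\\| across lags; the signed mode
    averages raw weights and takes the absolute value afterwards.
    """
    if not models:
        raise ParameterError("need at least one fitted model")
    ref = models[0].manifest
    for m in models[1:]:
        if ([tuple(s) for s in m.manifest["source_index"]]
                != [tuple(s) for s in ref["source_index"]]
                or m.manifest["n_lags"] != ref["n_lags"]):
            raise ContractError("fold models do not share a column manifest")
        if m.muscle_names != models[0].muscle_names:
            raise ContractError("fold models do not share muscle names")
    source_index = [tuple(s) for s in ref["source_index"]]
    channels = list(dict.fromkeys(ch for ch, _ in source_index))
    band_names = list(dict.fromkeys(b for _, b in source_index))
    for ch in channels:
        if ch not in layout.location_of_channel:
            raise ContractError(f"layout lacks a location for channel {ch!r}")
    locations = layout.locations
    loc_of = {ch: int(layout.location_of_channel[ch]) for ch in channels}

    records = []
    for fold, model in enumerate(models):
        # [K x M x N] -> lag-average -> [K x M]
        w = model.weights if signed else np.abs(model.weights)
        lag_avg = w.mean(axis=2)
        if signed:
            lag_avg = np.abs(lag_avg)
        for k, muscle in enumerate(model.muscle_names):
            cell = np.zeros((len(band_names), len(locations)))
            count = np.zeros_like(cell)
            for src, (ch, band) in enumerate(source_index):
                bi = band_names.index(band)
                li = locations.index(loc_of[ch])
                cell[bi, li] += lag_avg[k, src]
                count[bi, li] += 1
            with np.errstate(invalid="ignore"):
                cell = np.where(count > 0, cell / np.maximum(count, 1), np.nan)
            vmax = np.nanmax(cell)
            norm = cell / vmax if vmax > 0 else cell
            for bi, band in enumerate(band_names):
                for li, loc in enumerate(locations):
                    if count[bi, li] > 0:
                        records.append({"fold": fold, "muscle": muscle,
                                        "band": band, "location": loc,
                                        "value": float(norm[bi, li])})
    table = pd.DataFrame(records)
    return WeightSummary(table=table, band_names=band_names, locations=locations,
                         muscle_names=list(models[0].muscle_names),
                         n_folds=len(models))


def export_anova_table(summary: WeightSummary, path=None) -> pd.DataFrame:
    """Long-format (fold, muscle, band, location, value) table; one row per cell."""
    cols = ["fold", "muscle", "band", "location", "value"]
    df = summary.table[cols].copy() if len(summary.table) else pd.DataFrame(columns=cols)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def import_anova_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != ["fold", "muscle", "band", "location", "value"]:
        raise ParameterError("not a weight-summary export")
    return df
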