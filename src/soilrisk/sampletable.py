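"""Sample container for multi-element soil surveys.

A :class:`SampleTable` holds the samples x elements concentration matrix
(mg/kg) together with the per-sample soil properties that drive the Dutch
threshold corrections (clay %, organic matter %), optional planar
coordinates, and a per-cell censoring mask for values below the method
detection limit (MDL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SampleTable"]


@dataclass
class SampleTable:
    """Samples x elements soil-concentration table.

    Parameters
    ----------
    conc : pandas.DataFrame
        Concentrations in mg/kg, index = sample ids, columns = element
        symbols. Censored cells hold the substitute value (not the raw
        below-detection reading).
    clay : pandas.Series
        Percent particles < 2 um, aligned to ``conc.index``.
    om : pandas.Series
        Percent organic matter, aligned to ``conc.index``.
    censored : pandas.DataFrame, optional
        Boolean mask, True where the measurement fell below the MDL.
    x, y : pandas.Series, optional
        Planar coordinates.
    """

    conc: pd.DataFrame
    clay: pd.Series
    om: pd.Series
    censored: pd.DataFrame | None = None
    x: pd.Series | None = None
    y: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.censored is None:
            self.censored = pd.DataFrame(
                False, index=self.conc.index, columns=self.conc.columns
            )
        self.clay = pd.Series(self.clay, index=self.conc.index, dtype=float)
        self.om = pd.Series(self.om, index=self.conc.index, dtype=float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        conc = self.conc.to_numpy(dtype=float)
        cens = self.censored.to_numpy(dtype=bool)
        if not np.all(conc[~cens] >= 0):
            raise ValueError("negative uncensored concentration")
        for name, s in (("clay", self.clay), ("om", self.om)):
            if ((s < 0) | (s > 100)).any():
                raise ValueError(f"{name} outside [0, 100] %")
        if list(self.censored.columns) != list(self.conc.columns):
            raise ValueError("censored mask columns differ from conc columns")

    # -- convenience ------------------------------------------------------
    @property
    def elements(self) -> list[str]:
        return list(self.conc.columns)

    @property
    def n_samples(self) -> int:
        return len(self.conc)

    def __len__(self) -> int:
        return self.n_samples

    # -- I/O --------------------------------------------------------------
    def to_csv(self, path: str | Path, mdl_label: str = "<MDL") -> None:
        """Write as CSV with censored cells encoded as ``<MDL`` and a
        sidecar ``*.censored.csv`` boolean table."""
        path = Path(path)
        out = self.conc.astype(object).copy()
        out[self.censored] = mdl_label
        frame = pd.DataFrame(index=self.conc.index)
        frame.index.name = "sample_id"
        if self.x is not None:
            frame["x"] = self.x
        if self.y is not None:
            frame["y"] = self.y
        frame = pd.concat([frame, out], axis=1)
        frame["clay_pct"] = self.clay
        frame["om_pct"] = self.om
        frame.to_csv(path)
        self.censored.rename_axis("sample_id").to_csv(
            path.with_suffix(".censored.csv")
        )

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        mdl_substitute: dict[str, float] | None = None,
        mdl_label: str = "<MDL",
    ) -> "SampleTable":
        """Read a table written by :meth:`to_csv`.

        Censored cells are restored from the sidecar mask when present;
        otherwise cells equal to ``mdl_label`` are flagged and replaced by
        ``mdl_substitute[element]`` (required in that case).
        """
        path = Path(path)
        frame = pd.read_csv(path, index_col="sample_id")
        meta_cols = [c for c in ("x", "y", "clay_pct", "om_pct") if c in frame]
        elem_cols = [c for c in frame.columns if c not in meta_cols]
        raw = frame[elem_cols]
        sidecar = path.with_suffix(".censored.csv")
        if sidecar.exists():
            censored = pd.read_csv(sidecar, index_col="sample_id")[elem_cols].astype(bool)
        else:
            censored = raw.astype(str).eq(mdl_label)
        conc = raw.copy()
        if censored.to_numpy().any():
            for el in elem_cols:
                mask = censored[el]
                if mask.any():
                    labelled = raw[el].astype(str).eq(mdl_label)
                    if labelled.any():
                        if mdl_substitute is None or el not in mdl_substitute:
                            raise ValueError(
                                f"censored cells for {el} need an MDL substitute"
                            )
                        conc.loc[labelled, el] = mdl_substitute[el]
        conc = conc.astype(float)
        return cls(
            conc=conc,
            clay=frame["clay_pct"],
            om=frame["om_pct"],
            censored=censored,
            x=frame["x"] if "x" in frame else None,
            y=frame["y"] if "y" in frame else None,
        )
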