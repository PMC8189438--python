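"""Long-format CSV I/O and table-level baseline correction.

LC-MS peak areas travel as long tables with columns ``sample_id, group,
metabolite, isotopologue, peak_area``; corrected output adds
``corrected_fraction`` per isotopologue and the per-sample
``summed_labeled_fraction``.  Every file written here carries a provenance
header (``# key: value`` comment lines) recording the seed, config hash and
package version.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from . import __version__
from .isotopes import PairingError, PeakAreaVector, baseline_correct

__all__ = [
    "PEAK_AREA_COLUMNS",
    "read_table",
    "write_table",
    "correct_table",
    "summarize_labeled_fractions",
]

PEAK_AREA_COLUMNS = ["sample_id", "group", "metabolite", "isotopologue", "peak_area"]


def provenance_header(seed=None, config=None, extra=None) -> str:
    """Comment lines identifying the run: version, seed, config hash."""
    lines = [f"# c1trace_version: {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        lines.append(f"# config_sha256: {digest}")
    for key, value in (extra or {}).items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


def write_table(df: pd.DataFrame, path, seed=None, config=None, extra=None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, config=config, extra=extra))
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path, required=()) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def _area_vectors(df: pd.DataFrame, n_max=None):
    """Yield one PeakAreaVector per (sample, metabolite), dense in m+0..m+n."""
    for (sample_id, metabolite), grp in df.groupby(
        ["sample_id", "metabolite"], sort=True
    ):
        limit = None if n_max is None else n_max.get(metabolite)
        top = int(grp["isotopologue"].max())
        if limit is not None and top > limit:
            raise ValueError(
                f"{metabolite}: isotopologue m+{top} exceeds carbon count {limit}"
            )
        size = (top if limit is None else limit) + 1
        areas = np.zeros(size)
        areas[grp["isotopologue"].to_numpy()] = grp["peak_area"].to_numpy()
        group = str(grp["group"].iloc[0]) if "group" in grp else ""
        yield PeakAreaVector(metabolite, areas, sample_id=str(sample_id), group=group)


def _control_baseline(control: pd.DataFrame, n_max=None) -> dict:
    """Mean control isotopologue fractions per metabolite.

    Replicate unlabeled samples are averaged (as fractions, so samples with
    different total intensity weigh equally) before subtraction.
    """
    sums = {}
    for pa in _area_vectors(control, n_max=n_max):
        fr = pa.areas / pa.areas.sum()
        acc = sums.setdefault(pa.metabolite, [])
        acc.append(fr)
    baselines = {}
    for metabolite, stack in sums.items():
        width = max(v.size for v in stack)
        mean = np.mean(
            [np.pad(v, (0, width - v.size)) for v in stack], axis=0
        )
        baselines[metabolite] = mean / mean.sum()
    return baselines


def correct_table(
    labeled: pd.DataFrame,
    control: pd.DataFrame,
    clamp: bool = True,
    n_max: dict | None = None,
) -> pd.DataFrame:
    """Baseline-correct a labeled peak-area table against unlabeled controls.

    Returns a long table with one row per (sample, metabolite, isotopologue
    >= 1) holding the corrected 13C fraction, plus the per-sample summed
    labeled fraction repeated on each row.  Metabolites lacking a control
    raise a pairing error.
    """
    baselines = _control_baseline(control, n_max=n_max)
    rows = []
    for pa in _area_vectors(labeled, n_max=n_max):
        if pa.metabolite not in baselines:
            raise PairingError(f"no unlabeled control for {pa.metabolite!r}")
        base = baselines[pa.metabolite]
        width = max(pa.areas.size, base.size)
        sample_pa = PeakAreaVector(
            pa.metabolite,
            np.pad(pa.areas, (0, width - pa.areas.size)),
            sample_id=pa.sample_id,
            group=pa.group,
        )
        control_pa = PeakAreaVector(
            pa.metabolite, np.pad(base, (0, width - base.size))
        )
        corr = baseline_correct(sample_pa, control_pa, clamp=clamp)
        for n, value in enumerate(corr.corrected, start=1):
            rows.append(
                {
                    "sample_id": pa.sample_id,
                    "group": pa.group,
                    "metabolite": pa.metabolite,
                    "isotopologue": n,
                    "corrected_fraction": value,
                    "summed_labeled_fraction": corr.summed_labeled_fraction,
                }
            )
    return pd.DataFrame(rows)


def summarize_labeled_fractions(corrected: pd.DataFrame) -> pd.DataFrame:
    """Group mean and SD of the summed labeled fraction per metabolite."""
    per_sample = corrected.drop_duplicates(["sample_id", "metabolite"])[
        ["sample_id", "group", "metabolite", "summed_labeled_fraction"]
    ]
    out = (
        per_sample.groupby(["metabolite", "group"])["summed_labeled_fraction"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    return out
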