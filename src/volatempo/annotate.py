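"""Component annotation: spectral library matching and Kovats retention
indices, bridging PARAFAC2 factors to a longitudinal peak table."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parafac2 import Parafac2Results
from .simulate import PEAK_TABLE_COLUMNS

__all__ = [
    "CompoundAnnotation",
    "match_spectrum",
    "kovats_ri",
    "annotate_components",
    "build_peak_table",
]


def _as_peaks(spectrum) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(spectrum, "peaks"):  # matchms Spectrum
        return np.asarray(spectrum.peaks.mz, dtype=float), np.asarray(
            spectrum.peaks.intensities, dtype=float
        )
    mz, intensities = spectrum
    return np.asarray(mz, dtype=float), np.asarray(intensities, dtype=float)


def _weighted_vector(mz, intensities, mz_power, intensity_power):
    w = np.power(mz, mz_power) * np.power(np.clip(intensities, 0.0, None),
                                          intensity_power)
    return w


def spectral_match_score(query, reference, mz_power: float = 1.0,
                         intensity_power: float = 0.5) -> float:
    """Weighted cosine similarity between two spectra.

    Peaks are aligned on exact m/z values (unit-mass bins in this pipeline)
    and weighted as ``m/z^a · intensity^b``; the default a=1, b=0.5 is the
    classic identity-search weighting that de-emphasises low-mass fragments.
    Scores lie in [0, 1]; identical spectra score 1, spectra on disjoint m/z
    sets score 0.
    """
    qmz, qint = _as_peaks(query)
    rmz, rint = _as_peaks(reference)
    if qint.size == 0 or not np.any(qint > 0):
        raise ValueError("query spectrum has all-zero intensities")
    union = np.union1d(qmz, rmz)
    qv = np.zeros(union.size)
    rv = np.zeros(union.size)
    qv[np.searchsorted(union, qmz)] = _weighted_vector(qmz, qint, mz_power,
                                                       intensity_power)
    rv[np.searchsorted(union, rmz)] = _weighted_vector(rmz, rint, mz_power,
                                                       intensity_power)
    nq, nr = np.linalg.norm(qv), np.linalg.norm(rv)
    if nq == 0.0 or nr == 0.0:
        return 0.0
    return float(np.clip(qv @ rv / (nq * nr), 0.0, 1.0))


def match_spectrum(spectrum, library: Sequence, mz_power: float = 1.0,
                   intensity_power: float = 0.5) -> list[tuple[str, float]]:
    """Rank library entries by weighted-cosine similarity to a spectrum.

    Returns ``[(name, score), ...]`` in descending score order (name as
    secondary key for deterministic ties).
    """
    if not library:
        raise ValueError("library is empty")
    scored = []
    for entry in library:
        name = entry.get("compound_name") if hasattr(entry, "get") else None
        if name is None:
            name = getattr(entry, "name", "unknown")
        scored.append(
            (str(name), spectral_match_score(spectrum, entry, mz_power,
                                             intensity_power))
        )
    return sorted(scored, key=lambda t: (-t[1], t[0]))


def kovats_ri(retention_time: float, alkane_ladder: Sequence[tuple[int, float]],
              extrapolate: bool = False) -> float:
    """Temperature-programmed (linear) Kovats retention index.

    ``RI = 100·n + 100·(t − t_n)/(t_{n+1} − t_n)`` for the alkanes bracketing
    the analyte.  Retention times outside the ladder raise unless
    ``extrapolate`` is enabled (nearest segment extended linearly).
    """
    ladder = sorted(alkane_ladder)
    carbons = np.array([c for c, _t in ladder], dtype=float)
    times = np.array([t for _c, t in ladder], dtype=float)
    if ladder[0][1] >= ladder[-1][1] or np.any(np.diff(times) <= 0):
        raise ValueError("alkane ladder retention times must be strictly increasing")
    t = float(retention_time)
    if (t < times[0] or t > times[-1]) and not extrapolate:
        raise ValueError(
            f"retention time {t} min outside ladder range "
            f"[{times[0]}, {times[-1]}]; enable extrapolate to override"
        )
    idx = int(np.clip(np.searchsorted(times, t, side="right") - 1, 0,
                      times.size - 2))
    n, tn = carbons[idx], times[idx]
    n1, tn1 = carbons[idx + 1], times[idx + 1]
    return float(100.0 * n + 100.0 * (n1 - n) * (t - tn) / (tn1 - tn))


@dataclass
class CompoundAnnotation:
    """Identity assignment for one PARAFAC2 component."""

    component: int
    name: str
    score: float
    apex_rt_min: float
    kovats_ri: float | None = None
    ri_agreement: bool | None = None
    identified: bool = True


def annotate_components(results: Parafac2Results, library: Sequence,
                        ladder: Sequence[tuple[int, float]] | None = None,
                        min_score: float = 0.6, ri_tolerance: float = 30.0,
                        mz_power: float = 1.0, intensity_power: float = 0.5
                        ) -> list[CompoundAnnotation]:
    """Annotate every component of a fitted model against an MSP library.

    The component's estimated spectrum is matched by weighted cosine; the
    consensus apex retention time is converted to a Kovats index when an
    alkane ladder is supplied, and compared to the library's retention index
    (agreement within ``ri_tolerance`` index units) as an orthogonal
    identity check.  Components scoring below ``min_score`` keep a neutral
    ``component_<f>`` name and are flagged unidentified.
    """
    mz_axis = np.asarray(results.model.tensor.mz_axis, dtype=float)
    apexes = results.apex_retention_times()
    ri_by_name = {}
    for entry in library:
        ri = entry.get("retention_index") if hasattr(entry, "get") else None
        name = entry.get("compound_name") if hasattr(entry, "get") else None
        if name is not None and ri is not None:
            ri_by_name[str(name)] = float(ri)
    annotations = []
    for f in range(results.n_components):
        ranked = match_spectrum((mz_axis, results.spectra[:, f]), library,
                                mz_power, intensity_power)
        name, score = ranked[0]
        identified = score >= min_score
        ri = None
        agreement = None
        if ladder is not None:
            try:
                ri = kovats_ri(apexes[f], ladder)
            except ValueError:
                ri = None
            lib_ri = ri_by_name.get(name)
            if ri is not None and lib_ri is not None:
                agreement = abs(ri - lib_ri) <= ri_tolerance
        annotations.append(
            CompoundAnnotation(
                component=f,
                name=name if identified else f"component_{f}",
                score=score,
                apex_rt_min=float(apexes[f]),
                kovats_ri=ri,
                ri_agreement=agreement,
                identified=identified,
            )
        )
    return annotations


def build_peak_table(models: Mapping[str, Parafac2Results],
                     annotations: Mapping[str, Sequence[CompoundAnnotation]],
                     sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Assemble a long-format peak table from deconvolved intervals.

    One row per (sample, annotated component); the intensity is the
    component's concentration loading.  Design metadata (group, replicate,
    time) is joined by sample id; a sample present in a tensor but absent
    from the metadata is an error.  Compound names repeated across intervals
    are disambiguated with a deterministic numeric suffix.
    """
    required = {"sample_id", "group", "replicate", "time_h"}
    missing = required - set(sample_meta.columns)
    if missing:
        raise ValueError(f"sample metadata lacks columns: {sorted(missing)}")
    meta = sample_meta.set_index("sample_id")
    name_counts: dict[str, int] = {}
    rows = []
    for interval in sorted(models):
        res = models[interval]
        anns = sorted(annotations[interval], key=lambda a: a.component)
        sample_ids = res.model.tensor.sample_ids
        for sid in sample_ids:
            if sid not in meta.index:
                raise ValueError(f"sample {sid!r} missing from design metadata")
        for ann in anns:
            n_seen = name_counts.get(ann.name, 0)
            label = ann.name if n_seen == 0 else f"{ann.name} ({n_seen + 1})"
            name_counts[ann.name] = n_seen + 1
            for k, sid in enumerate(sample_ids):
                m = meta.loc[sid]
                rows.append(
                    (
                        sid,
                        m["group"],
                        m["replicate"],
                        float(m["time_h"]),
                        label,
                        float(res.concentrations[k, ann.component]),
                    )
                )
    table = pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)
    return table.sort_values(["compound", "sample_id"], kind="stable").reset_index(
        drop=True
    )
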