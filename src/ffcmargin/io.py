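"""CSV/JSON interchange formats.

All tables are plain UTF-8 CSV with a header row and '.' decimal separator:

* decay curves — ``sample_id, field_mhz, delay_s, mz`` (long format);
* NMRD profiles — ``sample_id, field_mhz, r1_s1[, uncertainty_s1]``;
* samples — ``sample_id, mass_mg, f_adipose, f_stroma, f_tumour, true_class``;
* fit report — ``sample_id, field_mhz, t1_s, r1_s1, rss, converged``;
* quantifiers — ``sample_id, ratio, two_r1_s1`` (blank 2R1 = not measured);
* decisions — ``sample_id, predicted, path, quadrant``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import Decision
from .quantifiers import QuantifierSet
from .relaxometry import DecayCurve, NMRDProfile, T1Fit
from .synthetic import TissueSample


def write_decay_curves(curves: list[DecayCurve], path) -> None:
    rows = [
        {"sample_id": c.sample_id, "field_mhz": c.field_mhz, "delay_s": d, "mz": m}
        for c in curves
        for d, m in zip(c.delays_s, c.mz)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_decay_curves(path) -> list[DecayCurve]:
    df = pd.read_csv(path)
    curves = []
    for (sid, f), g in df.groupby(["sample_id", "field_mhz"], sort=True):
        g = g.sort_values("delay_s")
        curves.append(
            DecayCurve(str(sid), float(f), g["delay_s"].to_numpy(), g["mz"].to_numpy())
        )
    return curves


def write_profiles(profiles: list[NMRDProfile], path) -> None:
    rows = []
    for p in profiles:
        unc = p.uncertainty_s1 if p.uncertainty_s1 is not None else [np.nan] * len(p.fields_mhz)
        for f, r, u in zip(p.fields_mhz, p.r1_s1, unc):
            rows.append(
                {"sample_id": p.sample_id, "field_mhz": f, "r1_s1": r, "uncertainty_s1": u}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles(path) -> list[NMRDProfile]:
    df = pd.read_csv(path)
    out = []
    for sid, g in df.groupby("sample_id", sort=True):
        g = g.sort_values("field_mhz")
        unc = None
        if "uncertainty_s1" in g and g["uncertainty_s1"].notna().all():
            unc = g["uncertainty_s1"].to_numpy()
        out.append(
            NMRDProfile(str(sid), g["field_mhz"].to_numpy(), g["r1_s1"].to_numpy(), unc)
        )
    return out


def write_samples(samples: list[TissueSample], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "mass_mg": s.mass_mg,
                "f_adipose": s.f_adipose,
                "f_stroma": s.f_stroma,
                "f_tumour": s.f_tumour,
                "true_class": s.true_class,
            }
            for s in samples
        ]
    ).to_csv(path, index=False)


def read_samples(path) -> list[TissueSample]:
    df = pd.read_csv(path)
    return [
        TissueSample(
            sample_id=str(r.sample_id),
            mass_mg=float(r.mass_mg),
            f_adipose=float(r.f_adipose),
            f_stroma=float(r.f_stroma),
            f_tumour=float(r.f_tumour),
        )
        for r in df.itertuples()
    ]


def write_fit_report(fits: list[T1Fit], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": f.sample_id,
                "field_mhz": f.field_mhz,
                "t1_s": f.t1_s,
                "r1_s1": f.r1_s1,
                "rss": f.rss,
                "converged": f.converged,
            }
            for f in fits
        ]
    ).to_csv(path, index=False)


def write_quantifiers(qsets: list[QuantifierSet], path) -> None:
    pd.DataFrame(
        [
            {"sample_id": q.sample_id, "ratio": q.ratio, "two_r1_s1": q.two_r1}
            for q in qsets
        ]
    ).to_csv(path, index=False)


def read_quantifiers(path) -> list[QuantifierSet]:
    df = pd.read_csv(path)
    return [
        QuantifierSet(
            sample_id=str(r.sample_id),
            ratio=float(r.ratio),
            two_r1=None if pd.isna(r.two_r1_s1) else float(r.two_r1_s1),
        )
        for r in df.itertuples()
    ]


def write_decisions(decisions: list[Decision], path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": d.sample_id,
                "predicted": d.predicted,
                "path": d.path,
                "quadrant": d.quadrant,
            }
            for d in decisions
        ]
    ).to_csv(path, index=False)


def read_decisions(path) -> list[Decision]:
    df = pd.read_csv(path)
    return [
        Decision(
            sample_id=str(r.sample_id),
            predicted=str(r.predicted),
            path=str(r.path),
            quadrant=None if pd.isna(r.quadrant) else str(r.quadrant),
        )
        for r in df.itertuples()
    ]


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
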