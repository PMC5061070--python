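"""Wrist muscle parameters: geometry (moment arms) and strength (PCSA).

Six primary muscles actuate the wrist's two rotational degrees of freedom:
flexor carpi radialis (FCR), flexor carpi ulnaris (FCU), extensor carpi
radialis longus (ECRL), extensor carpi radialis brevis (ECRB), extensor
carpi ulnaris (ECU) and abductor pollicis longus (APL).

Sign convention (ISB): flexion positive about the flexion-extension (FE)
axis, ulnar deviation positive about the radioulnar-deviation (RUD) axis.
A positive moment arm means tension in that tendon produces positive torque
about that axis.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MUSCLE_NAMES = ("FCR", "FCU", "ECRL", "ECRB", "ECU", "APL")

#: Maximal muscle stress (specific tension), N per cm^2 of PCSA.
SPECIFIC_TENSION = 25.0


@dataclass(frozen=True)
class MuscleParams:
    """Per-muscle geometry and strength.

    Parameters
    ----------
    name : str
        One of ``MUSCLE_NAMES``.
    pcsa : float
        Physiological cross-sectional area, cm^2. Strictly positive.
    r_fe : float
        Signed moment arm about the FE axis, mm (flexion positive).
    r_rud : float
        Signed moment arm about the RUD axis, mm (ulnar deviation positive).
    f_max : float
        Maximal tendon force, N. Defaults to ``SPECIFIC_TENSION * pcsa``.
    """

    name: str
    pcsa: float
    r_fe: float
    r_rud: float
    f_max: float = -1.0  # sentinel: computed from pcsa in __post_init__

    def __post_init__(self) -> None:
        if self.name not in MUSCLE_NAMES:
            raise ValueError(f"unknown muscle name {self.name!r}")
        if not self.pcsa > 0:
            raise ValueError(f"{self.name}: pcsa must be > 0, got {self.pcsa}")
        if self.f_max < 0:
            object.__setattr__(self, "f_max", SPECIFIC_TENSION * self.pcsa)
        if not self.f_max > 0:
            raise ValueError(f"{self.name}: f_max must be > 0, got {self.f_max}")


class MuscleSet:
    """An ordered collection of the six wrist muscles.

    Exposes the quantities the plant and controllers need as arrays:
    ``moment_arms`` (n x 2, mm; columns FE, RUD), ``pcsa`` (cm^2) and
    ``f_max`` (N).
    """

    def __init__(self, muscles: list[MuscleParams]):
        if len({m.name for m in muscles}) != len(muscles):
            raise ValueError("duplicate muscle names")
        self.muscles = list(muscles)
        self.names = tuple(m.name for m in muscles)
        self.moment_arms = np.array([[m.r_fe, m.r_rud] for m in muscles], float)
        self.pcsa = np.array([m.pcsa for m in muscles], float)
        self.f_max = np.array([m.f_max for m in muscles], float)
        if np.linalg.matrix_rank(self.moment_arms) < 2:
            raise ValueError("moment-arm matrix must have rank 2 "
                             "(both wrist axes must be actuatable)")

    def __len__(self) -> int:
        return len(self.muscles)

    def __iter__(self):
        return iter(self.muscles)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "pcsa_cm2": self.pcsa,
                "r_fe_mm": self.moment_arms[:, 0],
                "r_rud_mm": self.moment_arms[:, 1],
                "f_max_N": self.f_max,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_muscle_table(source: str | Path | io.IOBase) -> MuscleSet:
    """Read a muscle table from delimited text.

    Expected header: ``name,pcsa_cm2,r_fe_mm,r_rud_mm,f_max_N``. A blank
    ``f_max_N`` entry is filled as ``SPECIFIC_TENSION * pcsa``.
    """
    df = pd.read_csv(source)
    required = {"name", "pcsa_cm2", "r_fe_mm", "r_rud_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"muscle table missing columns: {sorted(missing)}")
    muscles = []
    for _, row in df.iterrows():
        f_max = row.get("f_max_N", np.nan)
        if pd.isna(f_max):
            f_max = -1.0  # MuscleParams fills from pcsa
        muscles.append(
            MuscleParams(
                name=str(row["name"]),
                pcsa=float(row["pcsa_cm2"]),
                r_fe=float(row["r_fe_mm"]),
                r_rud=float(row["r_rud_mm"]),
                f_max=float(f_max),
            )
        )
    return MuscleSet(muscles)


def default_muscles() -> MuscleSet:
    """The default wrist muscle table.

    Moment arms and PCSAs are literature-plausible magnitudes (arms 4-17 mm,
    PCSAs 1.9-3.4 cm^2) respecting the ISB sign convention: flexors (FCR,
    FCU) have positive FE arms, extensors negative; ulnar deviators (FCU,
    ECU) have positive RUD arms, radial deviators (FCR, ECRL, ECRB, APL)
    negative. f_max = 25 N/cm^2 x PCSA.
    """
    rows = [
        # name,  pcsa, r_fe, r_rud
        ("FCR", 2.0, 15.0, -5.0),
        ("FCU", 3.4, 17.0, 14.0),
        ("ECRL", 2.4, -10.0, -13.0),
        ("ECRB", 2.9, -14.0, -4.0),
        ("ECU", 2.6, -6.0, 17.0),
        ("APL", 1.9, -4.0, -15.0),
    ]
    return MuscleSet([MuscleParams(n, p, rf, rr) for n, p, rf, rr in rows])
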