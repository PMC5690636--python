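"""Synthetic CT-like nodule cohorts with controllable class structure.

The generator emulates the structure of a diagnostic CT nodule dataset —
per-patient nodule stacks of varying slice count with class-dependent 3D
intensity patterns — so the whole pipeline (preparation, training,
cross-validation) runs with no external download:

* **benign** (diagnosis code 1): a single smooth Gaussian ellipsoid;
* **primary malignant** (code 2): an ellipsoid whose radius is modulated by
  angular lobes, giving a spiculated margin;
* **metastatic malignant** (code 3): a mixture of several small offset blobs.

Intensities are on an arbitrary [0, 1] scale (not Hounsfield units) with
additive Gaussian noise.  A ``separation`` knob ("easy" | "hard") scales how
strongly the class geometries differ: "easy" uses distinct sizes/contrasts
and low noise, "hard" shrinks the differences and raises the noise.
Anatomical context (vessels, pleura, lung texture) is deliberately absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataprep import DIAG_BENIGN, DIAG_METASTATIC, DIAG_PRIMARY, NoduleStack

__all__ = ["SyntheticConfig", "generate_stack", "generate_cohort", "cohort_manifest"]

CLASS_DIAG = {
    "benign": DIAG_BENIGN,
    "primary": DIAG_PRIMARY,
    "metastatic": DIAG_METASTATIC,
}


@dataclass
class SyntheticConfig:
    """Cohort layout and per-class geometry of the generator.

    Defaults mimic the diagnostic-subset accounting of the motivating study:
    29 / 25 / 42 patients for the benign / primary / metastatic classes with
    a mean of roughly 6.4 / 6.8 / 10 nodules per patient (186 / 169 / 421
    lesions in expectation).  ``slice_range`` is inclusive and defaults to
    {3..12} so both the zero-padding (n < 6) and the slice-selection (n > 6)
    branches of the preparation pipeline are exercised.
    """

    n_patients: dict = field(
        default_factory=lambda: {"benign": 29, "primary": 25, "metastatic": 42}
    )
    nodules_per_patient: dict = field(
        default_factory=lambda: {"benign": 6.4, "primary": 6.8, "metastatic": 10.0}
    )
    slice_range: tuple[int, int] = (3, 12)
    image_size: int = 80
    center_jitter: int = 5
    noise_sd: float = 0.05
    separation: str = "easy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separation not in ("easy", "hard"):
            raise ValueError("separation must be 'easy' or 'hard'")
        if self.image_size < 16:
            raise ValueError("image_size too small")
        lo, hi = self.slice_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid slice_range")

    def geometry(self, class_label: str) -> dict:
        """Per-class shape parameters, scaled by the separation level."""
        if class_label not in CLASS_DIAG:
            raise ValueError(f"unknown class {class_label!r}")
        easy = self.separation == "easy"
        if class_label == "benign":
            return {"radius": 7.0, "amplitude": 0.55 if easy else 0.75}
        if class_label == "primary":
            return {
                "radius": 11.0 if easy else 9.0,
                "amplitude": 0.95 if easy else 0.8,
                "n_lobes": 6,
                "lobe_depth": 0.45 if easy else 0.15,
            }
        return {
            "radius": 4.0 if easy else 5.5,
            "amplitude": 0.9 if easy else 0.8,
            "n_blobs": (2, 4),
            "offset": 9.0 if easy else 5.0,
        }

    def effective_noise_sd(self) -> float:
        return self.noise_sd if self.separation == "easy" else max(self.noise_sd, 0.12)


def _blob(rr, cc, zz, center, radius, rz) -> np.ndarray:
    r2 = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / radius**2 + (
        zz - center[2]
    ) ** 2 / rz**2
    return np.exp(-0.5 * r2 * 4.0)


def generate_stack(
    class_label: str,
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    patient_id: str = "P0000",
    nodule_id: str = "N0000",
) -> NoduleStack:
    """One nodule stack of the given class.

    The stack has ``n`` slices (uniform over ``cfg.slice_range``) of size
    ``image_size`` squared; the nodule's intensity pattern is centered on the
    recorded (row, col) center, so with zero noise the benign pattern's slice
    maxima fall exactly on it.
    """
    geo = cfg.geometry(class_label)
    size = cfg.image_size
    lo, hi = cfg.slice_range
    n = int(rng.integers(lo, hi + 1))
    j = cfg.center_jitter
    center = (
        int(size // 2 + rng.integers(-j, j + 1)),
        int(size // 2 + rng.integers(-j, j + 1)),
    )
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    zc = (n - 1) / 2.0
    rz = max(n / 2.0, 1.0)
    vol = np.zeros((n, size, size), dtype=np.float64)
    zz = np.arange(n, dtype=np.float64)[:, None, None]
    rr3, cc3 = rr[None], cc[None]
    if class_label == "benign":
        vol = geo["amplitude"] * _blob(
            rr3, cc3, zz, (center[0], center[1], zc), geo["radius"], rz
        )
    elif class_label == "primary":
        theta = np.arctan2(rr3 - center[0], cc3 - center[1])
        phase = rng.uniform(0, 2 * np.pi)
        radius = geo["radius"] * (
            1.0 + geo["lobe_depth"] * np.cos(geo["n_lobes"] * theta + phase)
        )
        r2 = ((rr3 - center[0]) ** 2 + (cc3 - center[1]) ** 2) / radius**2 + (
            zz - zc
        ) ** 2 / rz**2
        vol = geo["amplitude"] * np.exp(-0.5 * r2 * 4.0)
    else:  # metastatic: several small offset blobs
        n_blobs = int(rng.integers(geo["n_blobs"][0], geo["n_blobs"][1] + 1))
        for _ in range(n_blobs):
            ang = rng.uniform(0, 2 * np.pi)
            dist = rng.uniform(0.4, 1.0) * geo["offset"]
            c = (
                center[0] + dist * np.sin(ang),
                center[1] + dist * np.cos(ang),
                zc + rng.uniform(-0.25, 0.25) * n,
            )
            vol += geo["amplitude"] * _blob(rr3, cc3, zz, c, geo["radius"], rz / 2)
    vol = np.clip(vol, 0.0, 1.0)
    sd = cfg.effective_noise_sd()
    if sd > 0:
        vol = vol + rng.normal(0.0, sd, size=vol.shape)
    diag = CLASS_DIAG[class_label]
    return NoduleStack(
        patient_id=patient_id,
        nodule_id=nodule_id,
        slices=[vol[i].astype(np.float32) for i in range(n)],
        center=center,
        nodule_diag=diag,
        patient_diag=diag,
    )


def generate_cohort(cfg: SyntheticConfig) -> list[NoduleStack]:
    """A patient cohort of nodule stacks with the configured class layout.

    Patient ids are unique across classes; each patient's nodule count is
    Poisson around the class mean (patients drawing 0 nodules are omitted).
    Fully determined by ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    stacks: list[NoduleStack] = []
    p_idx = 0
    for class_label in ("benign", "primary", "metastatic"):
        n_pat = cfg.n_patients.get(class_label, 0)
        mean_nod = cfg.nodules_per_patient.get(class_label, 1.0)
        for _ in range(n_pat):
            pid = f"P{p_idx:04d}"
            p_idx += 1
            n_nod = int(rng.poisson(mean_nod))
            for k in range(n_nod):
                stacks.append(
                    generate_stack(
                        class_label,
                        cfg,
                        rng,
                        patient_id=pid,
                        nodule_id=f"{pid}-N{k:03d}",
                    )
                )
    return stacks


def cohort_manifest(stacks, volume_paths: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-slice manifest table in the schema the preparation stage reads.

    One row per slice with patient/nodule ids, the in-slice nodule center
    (0-based), diagnosis codes, and either a ``volume_path`` + 0-based
    ``slice_index`` (when ``volume_paths`` maps nodule ids to files) or the
    slice index alone for in-memory use.
    """
    rows = []
    for stack in stacks:
        for i in range(stack.n_slices):
            rows.append(
                {
                    "patient_id": stack.patient_id,
                    "nodule_id": stack.nodule_id,
                    "volume_path": (volume_paths or {}).get(stack.nodule_id, ""),
                    "slice_index": i,
                    "center_row": stack.center[0],
                    "center_col": stack.center[1],
                    "nodule_diag": stack.nodule_diag,
                    "patient_diag": stack.patient_diag,
                }
            )
    return pd.DataFrame(rows)
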