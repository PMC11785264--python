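"""Digital DCE-MRI phantom: tissue maps, kinetics, and signal generation.

The simulation chain is

    label map  ->  Parker population AIF C_p(t)
               ->  extended-Tofts tissue concentration C_t(t)
               ->  spoiled-gradient-echo (SPGR) signal S(t)

producing a noiseless dynamic series whose Casorati matrix (pixels x frames)
has rank at most the number of distinct tissue-parameter tuples.  Ground-truth
images are real and non-negative; they are stored as complex with zero phase
because the encoding operators are complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TissueClass",
    "PhantomDefinition",
    "AcquisitionParams",
    "AIFModel",
    "DynamicSeries",
    "Ellipse",
    "Rectangle",
    "PhantomGeometry",
    "parker_aif",
    "extended_tofts_concentration",
    "spgr_signal",
    "build_phantom",
    "simulate_dynamic_series",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueClass:
    """One tissue type: relaxation plus extended-Tofts kinetic parameters.

    Parameters
    ----------
    label : int
        Integer id used in the phantom label map.
    T1 : float
        Native longitudinal relaxation time, seconds.
    Ktrans : float
        Volume transfer constant, 1/min.
    ve : float
        Extravascular-extracellular volume fraction (0..1).
    vp : float
        Plasma volume fraction (0..1).
    M0 : float
        Equilibrium magnetization, arbitrary units (default 1).
    """

    label: int
    T1: float
    Ktrans: float = 0.0
    ve: float = 0.0
    vp: float = 0.0
    M0: float = 1.0

    def __post_init__(self) -> None:
        if self.T1 <= 0:
            raise ValueError(f"T1 must be > 0, got {self.T1}")
        if self.Ktrans < 0:
            raise ValueError(f"Ktrans must be >= 0, got {self.Ktrans}")
        if not (0.0 <= self.ve <= 1.0):
            raise ValueError(f"ve must be in [0, 1], got {self.ve}")
        if not (0.0 <= self.vp <= 1.0):
            raise ValueError(f"vp must be in [0, 1], got {self.vp}")
        if self.ve + self.vp > 1.0 + 1e-12:
            raise ValueError(f"ve + vp must be <= 1, got {self.ve + self.vp}")
        if self.M0 <= 0:
            raise ValueError(f"M0 must be > 0, got {self.M0}")


@dataclass(frozen=True)
class PhantomDefinition:
    """Label map plus the tissue classes it references."""

    label_map: np.ndarray  # (N, N) integer
    classes: tuple[TissueClass, ...]
    N: int

    def __post_init__(self) -> None:
        lm = np.asarray(self.label_map)
        if self.N < 8:
            raise ValueError("phantom grid must be at least 8x8")
        if lm.shape != (self.N, self.N):
            raise ValueError("label_map shape does not match N")
        labels = {c.label for c in self.classes}
        if len(labels) != len(self.classes):
            raise ValueError("duplicate tissue labels")
        present = set(np.unique(lm).tolist())
        if not present <= labels:
            raise ValueError(f"labels {present - labels} lack a TissueClass")

    def class_for(self, label: int) -> TissueClass:
        for c in self.classes:
            if c.label == label:
                return c
        raise KeyError(label)


@dataclass(frozen=True)
class AcquisitionParams:
    """Contrast-agent administration and SPGR acquisition settings.

    Defaults follow a standard abdominal DCE protocol: r1 = 4.1 L/(mmol s),
    TR = 6.2 ms, FA = 20 deg, dose = 0.05 mmol/kg, one radial spoke every
    0.18 s.
    """

    r1: float = 4.1  # relaxivity, L mmol^-1 s^-1
    TR: float = 6.2e-3  # seconds
    FA: float = 20.0  # degrees
    dose: float = 0.05  # mmol/kg
    dt_spoke: float = 0.18  # seconds per spoke / frame
    n_frames_total: int = 1000

    def __post_init__(self) -> None:
        for name in ("r1", "TR", "FA", "dose", "dt_spoke", "n_frames_total"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.FA > 90.0:
            raise ValueError("FA must be in (0, 90] degrees")


#: Parker population parameters (t in minutes): two Gaussians plus a
#: sigmoid-modulated exponential washout, calibrated at 0.1 mmol/kg.
PARKER_POPULATION = {
    "A1": 0.809,  # mmol min
    "A2": 0.330,
    "T1": 0.17046,  # min
    "T2": 0.365,
    "sigma1": 0.0563,  # min
    "sigma2": 0.132,
    "alpha": 1.050,  # mmol
    "beta": 0.1685,  # 1/min
    "s": 38.078,  # 1/min
    "tau": 0.483,  # min
}


@dataclass(frozen=True)
class AIFModel:
    """Arterial input function: Parker population curve or a tabulated one.

    ``reference_dose`` is the dose at which the parameterization was
    calibrated; evaluation scales linearly by ``dose / reference_dose``.
    """

    kind: str = "parker"
    params: dict = field(default_factory=lambda: dict(PARKER_POPULATION))
    reference_dose: float = 0.1  # mmol/kg
    # tabulated mode
    table_times: np.ndarray | None = None  # seconds
    table_conc: np.ndarray | None = None  # mmol/L

    def __post_init__(self) -> None:
        if self.kind not in ("parker", "tabulated"):
            raise ValueError(f"unknown AIF kind {self.kind!r}")
        if self.reference_dose <= 0:
            raise ValueError("reference dose must be positive")
        if self.kind == "tabulated":
            if self.table_times is None or self.table_conc is None:
                raise ValueError("tabulated AIF needs table_times/table_conc")
            if np.any(np.asarray(self.table_conc) < 0):
                raise ValueError("tabulated AIF must be non-negative")


@dataclass
class DynamicSeries:
    """Complex Casorati matrix (N^2 pixels x T frames) with frame times."""

    data: np.ndarray  # complex, (N*N, T)
    frame_times: np.ndarray  # seconds, (T,)
    N: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.N * self.N:
            raise ValueError("data must be (N*N, T)")
        if self.data.shape[1] != self.frame_times.size:
            raise ValueError("frame count does not match frame_times")
        if self.frame_times.size > 1 and np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def frames(self) -> np.ndarray:
        """View as an (N, N, T) image stack."""
        return self.data.reshape(self.N, self.N, self.n_frames)


# ---------------------------------------------------------------------------
# kinetics and signal
# ---------------------------------------------------------------------------


def parker_aif(times, model: AIFModel | None = None, dose: float = 0.05):
    """Blood-plasma concentration C_p(t) in mmol/L at ``times`` (seconds).

    Evaluates the Parker population AIF (mixed Gaussians plus a
    sigmoid-gated exponential), scaled linearly by ``dose`` relative to the
    model's reference dose.  Zero for t <= 0 (pre-injection).
    """
    if model is None:
        model = AIFModel()
    if dose < 0:
        raise ValueError("dose must be non-negative")
    t = np.asarray(times, dtype=float)
    if t.ndim > 0 and t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("times must be non-decreasing")
    scale = dose / model.reference_dose

    if model.kind == "tabulated":
        cp = np.interp(t, model.table_times, model.table_conc, left=0.0, right=float(model.table_conc[-1]))
        return scale * np.where(t > 0, cp, 0.0)

    p = model.params
    tm = t / 60.0  # formula is parameterized in minutes
    with np.errstate(over="ignore"):
        g1 = p["A1"] / (p["sigma1"] * np.sqrt(2 * np.pi)) * np.exp(
            -((tm - p["T1"]) ** 2) / (2 * p["sigma1"] ** 2)
        )
        g2 = p["A2"] / (p["sigma2"] * np.sqrt(2 * np.pi)) * np.exp(
            -((tm - p["T2"]) ** 2) / (2 * p["sigma2"] ** 2)
        )
        washout = p["alpha"] * np.exp(-p["beta"] * tm) / (1.0 + np.exp(-p["s"] * (tm - p["tau"])))
    cp = g1 + g2 + washout
    return scale * np.where(tm > 0, cp, 0.0)


def extended_tofts_concentration(tc: TissueClass, cp, times):
    r"""Tissue concentration C_t(t) for the extended Tofts model.

        C_t(t) = vp C_p(t) + Ktrans \int_0^t C_p(u) exp(-kep (t-u)) du,
        kep = Ktrans / ve

    The convolution is evaluated by the exact recursive solution of the
    exchange ODE assuming C_p piecewise linear between samples, which is
    unbiased at any uniform step size.  ``times`` must be uniformly spaced
    (seconds); Ktrans is per minute.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(cp, dtype=float)
    if t.shape != c.shape:
        raise ValueError("times and cp must have the same shape")
    if tc.Ktrans > 0 and tc.ve == 0:
        raise ValueError("ve = 0 with Ktrans > 0: exchange term undefined")
    if tc.Ktrans == 0:
        return tc.vp * c
    if t.size > 1:
        dts = np.diff(t)
        if not np.allclose(dts, dts[0], rtol=1e-8, atol=1e-12):
            raise ValueError("times must be uniformly spaced")
        dt = dts[0] / 60.0  # minutes
    else:
        return tc.vp * c

    kep = tc.Ktrans / tc.ve  # 1/min
    a = kep * dt
    ea = np.exp(-a)
    # integral weights for piecewise-linear C_p on one step:
    #   E1 = int_0^dt e^{-kep (dt-s)} ds
    #   E2 = int_0^dt (s/dt) e^{-kep (dt-s)} ds
    E1 = -np.expm1(-a) / kep
    E2 = E1 - (1.0 - (1.0 + a) * ea) / (kep * a / dt) / dt  # = E1 - (1-(1+a)e^-a)/(kep^2 dt)
    J = np.zeros_like(c)
    for n in range(c.size - 1):
        J[n + 1] = J[n] * ea + c[n] * (E1 - E2) + c[n + 1] * E2
    return tc.vp * c + tc.Ktrans * J


def spgr_signal(T1: float, conc, acq: AcquisitionParams, M0: float = 1.0):
    """Steady-state spoiled gradient-echo signal for a concentration curve.

        R1(t) = 1/T1 + r1 C(t)
        S(t)  = M0 sin(FA) (1 - e^{-TR R1}) / (1 - cos(FA) e^{-TR R1})

    Strictly increasing in C for FA in (0, 90] degrees.
    """
    if T1 <= 0:
        raise ValueError("T1 must be positive")
    c = np.asarray(conc, dtype=float)
    fa = np.deg2rad(acq.FA)
    r1t = 1.0 / T1 + acq.r1 * c
    e = np.exp(-acq.TR * r1t)
    return M0 * np.sin(fa) * (1.0 - e) / (1.0 - np.cos(fa) * e)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse; center/semi-axes in pixel units."""

    cx: float
    cy: float
    rx: float
    ry: float

    def mask(self, N: int) -> np.ndarray:
        if not (0 <= self.cx - self.rx and self.cx + self.rx <= N and 0 <= self.cy - self.ry and self.cy + self.ry <= N):
            raise ValueError(f"ellipse {self} extends off the {N}x{N} grid")
        x, y = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
        return ((x + 0.5 - self.cx) / self.rx) ** 2 + ((y + 0.5 - self.cy) / self.ry) ** 2 <= 1.0


@dataclass(frozen=True)
class Rectangle:
    """Axis-aligned rectangle [x0, x1) x [y0, y1) in pixel units."""

    x0: float
    y0: float
    x1: float
    y1: float

    def mask(self, N: int) -> np.ndarray:
        if not (0 <= self.x0 < self.x1 <= N and 0 <= self.y0 < self.y1 <= N):
            raise ValueError(f"rectangle {self} extends off the {N}x{N} grid")
        x, y = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
        return (x + 0.5 >= self.x0) & (x + 0.5 < self.x1) & (y + 0.5 >= self.y0) & (y + 0.5 < self.y1)


#: uniform sampling ranges for the randomized background class
BACKGROUND_RANGES = {
    "T1": (0.5, 2.0),  # s
    "Ktrans": (0.0, 0.5),  # 1/min
    "ve": (0.1, 0.5),
    "vp": (0.0, 0.1),
}


@dataclass(frozen=True)
class PhantomGeometry:
    """Geometric phantom description: priority-ordered regions on an N x N grid.

    ``regions`` is a sequence of (shape, TissueClass); later regions overwrite
    earlier ones.  Pixels covered by no region belong to the background class
    — either ``background`` if given, or a class with uniformly drawn kinetic
    parameters (seeded) when ``random_background`` is set, so the number of
    distinct time curves stays controlled.
    """

    N: int
    regions: tuple[tuple[object, TissueClass], ...]
    background: TissueClass | None = None
    random_background: bool = False
    background_label: int = 0


def build_phantom(spec: PhantomGeometry, seed: int = 0) -> PhantomDefinition:
    """Rasterize a geometric phantom description into a PhantomDefinition.

    Deterministic given ``seed`` (only the optional random background class
    consumes randomness).  Raises if a requested region ends up empty or
    off-grid.
    """
    if len(spec.regions) < 0 or (len(spec.regions) == 0 and spec.background is None and not spec.random_background):
        raise ValueError("phantom needs at least a background class")
    if spec.background is not None:
        bg = spec.background
    elif spec.random_background:
        rng = np.random.default_rng(seed)
        bg = TissueClass(
            label=spec.background_label,
            T1=float(rng.uniform(*BACKGROUND_RANGES["T1"])),
            Ktrans=float(rng.uniform(*BACKGROUND_RANGES["Ktrans"])),
            ve=float(rng.uniform(*BACKGROUND_RANGES["ve"])),
            vp=float(rng.uniform(*BACKGROUND_RANGES["vp"])),
        )
    else:
        bg = TissueClass(label=spec.background_label, T1=1.0)
    if bg.label != spec.background_label:
        bg = replace(bg, label=spec.background_label)

    label_map = np.full((spec.N, spec.N), spec.background_label, dtype=np.int32)
    classes = {spec.background_label: bg}
    for shape, tc in spec.regions:
        if tc.label == spec.background_label:
            raise ValueError("region label collides with background label")
        m = shape.mask(spec.N)
        if not m.any():
            raise ValueError(f"region for label {tc.label} rasterizes to zero pixels")
        label_map[m] = tc.label
        classes[tc.label] = tc
    # priority painting may bury an earlier region entirely
    present = set(np.unique(label_map).tolist())
    for lab in classes:
        if lab not in present:
            raise ValueError(f"class {lab} occupies no pixels after painting")
    return PhantomDefinition(label_map=label_map, classes=tuple(classes.values()), N=spec.N)


# ---------------------------------------------------------------------------
# dynamic series
# ---------------------------------------------------------------------------


def simulate_dynamic_series(
    ph: PhantomDefinition,
    acq: AcquisitionParams,
    aif: AIFModel | None = None,
    onset_frame: int = 2,
) -> DynamicSeries:
    """Noiseless dynamic series for a phantom: one SPGR curve per tissue class.

    Frame times are (0, dt, 2 dt, ...).  Contrast arrives at
    ``frame_times[onset_frame]`` so every earlier frame is guaranteed
    pre-contrast baseline.  The Casorati matrix is an exact sum of
    (indicator x curve) outer products, hence has rank at most the number of
    distinct tissue-parameter tuples.
    """
    if aif is None:
        aif = AIFModel()
    T = acq.n_frames_total
    if not (0 <= onset_frame < T):
        raise ValueError("onset_frame out of range")
    times = np.arange(T) * acq.dt_spoke
    t_rel = times - times[onset_frame]

    cp = parker_aif(t_rel, aif, dose=acq.dose)
    data = np.zeros((ph.N * ph.N, T), dtype=np.complex128)
    flat_labels = np.asarray(ph.label_map).ravel()
    for tc in ph.classes:
        ct = extended_tofts_concentration(tc, cp, times)
        sig = spgr_signal(tc.T1, ct, acq, M0=tc.M0)
        data[flat_labels == tc.label, :] = sig[None, :]
    return DynamicSeries(data=data, frame_times=times, N=ph.N)
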