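"""Synthetic cohort generator for the stratification pipeline.

Emulates the data structure of a longitudinal small-vessel-disease cohort in
which a minority of subjects ("preVaD") convert to dementia within a 5-year
follow-up: template-space tissue probability maps, binary lacune masks,
Jacobian determinant maps, divergence-map series around a per-subject
mid-point anatomy, cognitive z-score trajectories and exponential conversion
times.

Planted structure (all configurable through :class:`EffectSpec`):

* convertors carry a fractional grey-matter reduction in the left striatum
  and left hippocampus, excess WMH probability in frontal white matter, and
  a higher lacune rate with a left-hemisphere bias;
* convertors split into four anatomical subtypes spanning a
  high-vascular/low-atrophy to low-vascular/high-atrophy (Alzheimer's-like)
  spectrum, each with its own Jacobian contraction pattern, hippocampal
  atrophy rate, WMH/lacune load, cognitive profile and conversion hazard;
* conversion times are exponential with the subtype (or background) hazard,
  administratively censored at 5 years, so group membership in the emitted
  cohort table is itself stochastic, as in the study design.

The per-subtype hazards are illustrative: the study reports only a mean time
to conversion, not subtype-specific hazards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import (
    FOLLOW_UP_YEARS,
    Atlas,
    CohortTable,
    SubjectRecord,
    TissueSet,
    Volume,
)

# Region geometry in units of a reference 32-voxel grid edge; left-hemisphere
# centres, mirrored across the x mid-plane for the right hemisphere.
_REGIONS_LEFT = {
    "putamen-L": ((9.0, 13.0, 16.0), 2.0),
    "caudate-L": ((12.0, 19.0, 16.0), 2.0),
    "thalamus-L": ((13.0, 13.0, 12.0), 2.0),
    "hippocampus-L": ((9.0, 8.0, 11.0), 2.2),
    "frontal-wm-L": ((10.0, 23.0, 19.0), 2.4),
    "centrum-semiovale-L": ((10.0, 16.0, 22.0), 2.4),
}
_REF_EDGE = 32.0

#: expected lacune count per region for the non-convertor group; convertors
#: multiply these by ``EffectSpec.lacune_group_scale`` and the subtype's
#: ``lacune_scale``.  Left-hemisphere rates are higher, mirroring the
#: asymmetry of strategic lacunar damage.
DEFAULT_LACUNE_RATES = {
    "putamen-L": 0.20, "putamen-R": 0.12,
    "caudate-L": 0.12, "caudate-R": 0.08,
    "thalamus-L": 0.18, "thalamus-R": 0.16,
    "hippocampus-L": 0.04, "hippocampus-R": 0.03,
    "frontal-wm-L": 0.10, "frontal-wm-R": 0.07,
    "centrum-semiovale-L": 0.18, "centrum-semiovale-R": 0.09,
}


@dataclass
class SubtypeProfile:
    """One anatomical endophenotype of the convertor group."""

    name: str
    wmh_scale: float
    lacune_scale: float
    hippo_rate: float  # fractional volume change / year in the hippocampi
    global_rate: float  # background fractional change / year, brain-wide
    jacobian_contraction: dict[str, float]  # region -> planted (1 - J)
    cog_intercepts: dict[str, float]
    cog_slopes: dict[str, float]  # z / year
    hazard: float  # conversion events / year


def default_subtype_profiles() -> tuple[SubtypeProfile, ...]:
    """Four profiles along the vascular <-> Alzheimer's-like spectrum.

    Subtype 1 is the vascular extreme (heavy WMH/lacune load, white-matter
    contraction, near-average baseline cognition with steep executive and
    processing-speed decline); subtype 4 is the Alzheimer's-like extreme
    (low vascular burden, strong hippocampal contraction, memory-loaded
    baseline deficits).  Subtypes 2 and 3 interpolate.
    """
    return (
        SubtypeProfile(
            name="vascular",
            wmh_scale=1.8, lacune_scale=2.0,
            hippo_rate=-0.005, global_rate=-0.012,
            jacobian_contraction={
                "frontal-wm-L": 0.20, "frontal-wm-R": 0.17,
                "centrum-semiovale-L": 0.20, "centrum-semiovale-R": 0.16,
            },
            cog_intercepts={"EF": -0.7, "PS": -0.4, "WM": 0.0, "LTM": -0.05, "global": -0.3},
            cog_slopes={"EF": -0.30, "PS": -0.35, "WM": -0.05, "LTM": -0.05, "global": -0.20},
            hazard=0.55,
        ),
        SubtypeProfile(
            name="mixed-vascular",
            wmh_scale=1.4, lacune_scale=1.2,
            hippo_rate=-0.012, global_rate=-0.010,
            jacobian_contraction={
                "frontal-wm-L": 0.12, "frontal-wm-R": 0.10,
                "thalamus-L": 0.14, "thalamus-R": 0.12,
            },
            cog_intercepts={"EF": -1.8, "PS": -2.0, "WM": -0.2, "LTM": -0.4, "global": -1.2},
            cog_slopes={"EF": -0.20, "PS": -0.20, "WM": -0.08, "LTM": -0.10, "global": -0.15},
            hazard=0.50,
        ),
        SubtypeProfile(
            name="mixed-ad",
            wmh_scale=1.1, lacune_scale=1.0,
            hippo_rate=-0.018, global_rate=-0.008,
            jacobian_contraction={
                "hippocampus-L": 0.15, "hippocampus-R": 0.13,
                "putamen-L": 0.12, "putamen-R": 0.10,
            },
            cog_intercepts={"EF": -1.1, "PS": -0.8, "WM": 0.3, "LTM": -0.25, "global": -0.6},
            cog_slopes={"EF": -0.12, "PS": -0.12, "WM": -0.12, "LTM": -0.15, "global": -0.12},
            hazard=0.45,
        ),
        SubtypeProfile(
            name="ad-like",
            wmh_scale=0.5, lacune_scale=0.5,
            hippo_rate=-0.030, global_rate=-0.006,
            jacobian_contraction={
                "hippocampus-L": 0.25, "hippocampus-R": 0.22,
                "caudate-L": 0.10, "caudate-R": 0.08,
            },
            cog_intercepts={"EF": -1.7, "PS": -1.7, "WM": -0.8, "LTM": -0.75, "global": -1.3},
            cog_slopes={"EF": -0.25, "PS": -0.25, "WM": -0.20, "LTM": -0.25, "global": -0.22},
            hazard=0.40,
        ),
    )


@dataclass
class EffectSpec:
    """All planted effect sizes and cohort-level simulation settings."""

    gm_reduction_fraction: float = 0.15
    gm_target_rois: tuple[str, ...] = ("putamen-L", "caudate-L", "hippocampus-L")
    wmh_excess: float = 0.20
    wmh_target_rois: tuple[str, ...] = ("frontal-wm-L", "frontal-wm-R")
    lacune_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LACUNE_RATES))
    lacune_group_scale: float = 1.8  # convertor multiplier on lacune rates
    subtype_profiles: tuple[SubtypeProfile, ...] = field(default_factory=default_subtype_profiles)
    background_hazard: float = 0.012  # events/year for planted non-convertors
    background_rate: float = -0.003  # fractional change / year, non-convertors
    noise_sd: float = 0.02  # voxel noise on tissue probability maps
    subject_scale_sd: float = 0.05  # per-subject anatomical size variability
    jacobian_noise_sd: float = 0.02
    divergence_noise_sd: float = 0.005
    cog_noise_sd: float = 0.30
    n_non: int = 97
    n_conv: int = 22
    n_timepoints: int = 4  # annual visits at years 0 .. n-1
    dropout_prob: float = 0.10  # per non-baseline visit
    midpoint_quantize: bool = False  # snap conversion dates to visit mid-points

    def validate(self) -> None:
        if not 0.0 <= self.gm_reduction_fraction <= 1.0:
            raise ValueError("gm_reduction_fraction must lie in [0, 1]")
        if not 0.0 <= self.wmh_excess <= 1.0:
            raise ValueError("wmh_excess must lie in [0, 1]")
        if any(r < 0 for r in self.lacune_rates.values()):
            raise ValueError("lacune rates must be non-negative")
        if self.background_hazard <= 0 or any(p.hazard <= 0 for p in self.subtype_profiles):
            raise ValueError("hazards must be positive")
        if self.n_non < 2 or self.n_conv < 2:
            raise ValueError("need at least 2 subjects per planted group")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must lie in [0, 1)")


@dataclass
class SyntheticSubject:
    """Ground truth bundle for one simulated subject."""

    record: SubjectRecord
    planted_group: str  # "preVaD" | "non-convertor" (planted, not observed)
    true_subtype: int | None  # 1..4 for planted convertors
    tissues: TissueSet | None
    jacobian: Volume | None
    true_rate_map: Volume | None
    divergence_series: list[tuple[float, Volume]]


def make_atlas(grid_shape: tuple[int, int, int] = (32, 32, 32),
               voxel_size_mm: float = 2.0) -> Atlas:
    """Deterministic geometric atlas with left/right mirrored spherical ROIs.

    Regions: putamen, caudate, thalamus, hippocampus, frontal white matter
    and centrum semiovale, each bilateral (12 named regions).  The striatum
    is the putamen+caudate union, available through
    :meth:`Atlas.region_mask` with ``"putamen-L+caudate-L"`` etc.
    """
    nx, ny, nz = grid_shape
    scale = (min(grid_shape) - 1) / (_REF_EDGE - 1)
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    labels = np.zeros(grid_shape, dtype=np.int32)
    names: dict[int, str] = {}
    label = 0
    for lname, ((cx, cy, cz), radius) in _REGIONS_LEFT.items():
        for side in ("L", "R"):
            label += 1
            name = lname if side == "L" else lname[:-1] + "R"
            x0 = cx * scale if side == "L" else (nx - 1) - cx * scale
            d2 = ((ix - x0) ** 2 + (iy - cy * scale) ** 2 + (iz - cz * scale) ** 2)
            sphere = d2 <= (radius * scale) ** 2
            if not sphere.any():
                raise ValueError(f"grid {grid_shape} too small: region {name!r} is empty")
            if (labels[sphere] != 0).any():
                raise ValueError(f"grid {grid_shape} too small: region {name!r} overlaps")
            labels[sphere] = label
            names[label] = name
    return Atlas(labels, names, voxel_size_mm)


def brain_mask(atlas: Atlas) -> np.ndarray:
    """Boolean ellipsoidal brain mask on the atlas grid."""
    shape = atlas.labels.shape
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    d2 = sum(((g - (n - 1) / 2.0) / (0.44 * n)) ** 2 for g, n in zip(grids, shape))
    return d2 <= 1.0


def make_template(atlas: Atlas) -> dict[str, Volume]:
    """Piecewise template tissue maps: WM core, GM shell, CSF rim.

    Deep grey nuclei and the hippocampi override the WM core with grey
    matter; a periventricular WM shell carries the baseline WMH probability.
    """
    shape = atlas.labels.shape
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    # normalised radial coordinate, 1.0 at the brain surface
    d = np.sqrt(sum(((g - (n - 1) / 2.0) / (0.44 * n)) ** 2 for g, n in zip(grids, shape)))
    gm = np.where((d >= 0.62) & (d < 0.88), 0.80, 0.02)
    wm = np.where(d < 0.62, 0.85, np.where(d < 0.88, 0.10, 0.0))
    csf = np.where((d >= 0.88) & (d <= 1.0), 0.75, np.where(d < 0.88, 0.03, 0.0))
    # periventricular WMH probability decaying outward, so scaling the map
    # moves both lesion intensity and the supra-threshold lesion extent
    wmh = np.clip(0.8 - 1.6 * d, 0.0, 1.0)
    gm = np.where(d > 1.0, 0.0, gm)
    wm = np.where(d > 1.0, 0.0, wm)
    grey_rois = ("putamen", "caudate", "thalamus", "hippocampus")
    for lab, name in atlas.names.items():
        if name.rsplit("-", 1)[0] in grey_rois:
            roi = atlas.labels == lab
            gm[roi] = 0.80
            wm[roi] = 0.05
            csf[roi] = 0.03
            wmh[roi] = 0.0
    wm = wm - wmh  # keep per-voxel tissue sum <= 1
    vs, tag = atlas.voxel_size_mm, atlas.space_tag
    return {k: Volume(v, vs, tag) for k, v in
            {"gm": gm, "wm": np.clip(wm, 0, 1), "csf": csf, "wmh": wmh}.items()}


def expected_conversion_probability(effects: EffectSpec) -> dict[str, float]:
    """Configured probability of conversion within follow-up, per planted group.

    Exponential event times censored at the follow-up horizon give
    ``1 - exp(-h * horizon)``; the convertor value averages over the four
    subtypes (subjects are assigned to subtypes uniformly).
    """
    t = FOLLOW_UP_YEARS
    conv = float(np.mean([1.0 - np.exp(-p.hazard * t) for p in effects.subtype_profiles]))
    non = float(1.0 - np.exp(-effects.background_hazard * t))
    return {"preVaD": conv, "non-convertor": non}


def place_lacunes(rng: np.random.Generator, atlas: Atlas, rates: dict[str, float]) -> np.ndarray:
    """Poisson lacune placement: each lacune is a 2-voxel blob inside its ROI."""
    mask = np.zeros(atlas.labels.shape, dtype=np.float64)
    for region, rate in sorted(rates.items()):
        if rate <= 0:
            continue
        n_lac = rng.poisson(rate)
        if n_lac == 0:
            continue
        voxels = np.argwhere(atlas.labels == atlas.label_of(region))
        vox_set = {tuple(v) for v in map(tuple, voxels)}
        for _ in range(n_lac):
            centre = tuple(voxels[rng.integers(len(voxels))])
            mask[centre] = 1.0
            # grow to a second in-region voxel so the lacune exceeds the
            # 10 mm^3 reporting threshold at 2 mm voxels
            for axis in rng.permutation(3):
                for step in (1, -1):
                    nb = list(centre)
                    nb[axis] += step
                    if tuple(nb) in vox_set:
                        mask[tuple(nb)] = 1.0
                        break
                else:
                    continue
                break
    return mask


def _simulate_record(rng: np.random.Generator, subject_id: str, planted_conv: bool,
                     profile: SubtypeProfile | None, effects: EffectSpec) -> SubjectRecord:
    if planted_conv:
        age = rng.normal(73.20, 9.38)
        nart = rng.normal(93.0, 14.96)
        male_p, mmse_mu, mmse_sd, mmse_lo = 0.7727, 26.0, 3.0, 16
        rankin_mu = 1.6
    else:
        age = rng.normal(69.49, 9.54)
        nart = rng.normal(100.03, 15.35)
        male_p, mmse_mu, mmse_sd, mmse_lo = 0.6082, 29.0, 1.5, 22
        rankin_mu = 1.1
    sex = "male" if rng.random() < male_p else "female"
    mmse = float(np.clip(np.round(rng.normal(mmse_mu, mmse_sd)), mmse_lo, 30))
    rankin = int(np.clip(rng.poisson(rankin_mu), 0, 5))

    hazard = profile.hazard if profile is not None else effects.background_hazard
    t_event = rng.exponential(1.0 / hazard)
    converted = t_event <= FOLLOW_UP_YEARS
    event_time = float(t_event) if converted else FOLLOW_UP_YEARS
    if converted and effects.midpoint_quantize:
        # conversion date recorded at the mid-point between surrounding visits
        event_time = float(np.floor(t_event) + 0.5)

    times = [0.0]
    for k in range(1, effects.n_timepoints):
        if rng.random() >= effects.dropout_prob:
            times.append(float(k))
    if len(times) < 2:  # every subject keeps at least one follow-up scan
        times.append(1.0)

    if planted_conv and profile is not None:
        intercepts, slopes = profile.cog_intercepts, profile.cog_slopes
    else:
        intercepts = {"EF": -0.78, "PS": -0.83, "WM": -0.16, "LTM": 0.01, "global": -0.49}
        slopes = {"EF": -0.05, "PS": -0.05, "WM": -0.02, "LTM": -0.02, "global": -0.04}
    cog = {
        dom: [intercepts[dom] + slopes[dom] * t + rng.normal(0, effects.cog_noise_sd)
              for t in times]
        for dom in ("EF", "PS", "WM", "LTM", "global")
    }
    return SubjectRecord(
        id=subject_id, age=float(age), sex=sex, nart=float(nart), rankin=rankin,
        tiv_mm3=0.0, scan_times=times, converted=bool(converted),
        event_time=event_time, mmse=mmse, cognitive_scores=cog,
    )


def simulate_subject(atlas: Atlas, effects: EffectSpec, group: str,
                     subtype: int | None, seed: int,
                     template: dict[str, Volume] | None = None,
                     subject_id: str = "s000",
                     longitudinal: bool = True) -> SyntheticSubject:
    """Simulate one subject's record, tissue maps and deformation data.

    ``group`` is the planted group ("preVaD" plants the convertor imaging
    phenotype); the emitted record's ``converted`` flag is drawn from the
    group's conversion hazard, so observed and planted group can disagree
    for a small fraction of subjects, as in a real cohort.
    """
    effects.validate()
    rng = np.random.default_rng(seed)
    if template is None:
        template = make_template(atlas)
    planted_conv = group == "preVaD"
    if planted_conv:
        if subtype is None or not 1 <= subtype <= len(effects.subtype_profiles):
            raise ValueError(f"unknown subtype id {subtype!r}")
        profile = effects.subtype_profiles[subtype - 1]
    else:
        profile = None

    record = _simulate_record(rng, subject_id, planted_conv, profile, effects)

    vs, tag = atlas.voxel_size_mm, atlas.space_tag
    gm = template["gm"].data.copy()
    wm = template["wm"].data.copy()
    csf = template["csf"].data.copy()
    wmh = template["wmh"].data.copy()

    if planted_conv:
        for roi in effects.gm_target_rois:
            m = atlas.labels == atlas.label_of(roi)
            gm[m] *= 1.0 - effects.gm_reduction_fraction
        wmh = np.clip(wmh * profile.wmh_scale, 0.0, 1.0)
        excess = effects.wmh_excess * profile.wmh_scale
        for roi in effects.wmh_target_rois:
            m = atlas.labels == atlas.label_of(roi)
            wmh[m] = np.clip(wmh[m] + excess, 0.0, 1.0)

    # per-subject anatomical size variability plus voxel noise
    scale = 1.0 + rng.normal(0.0, effects.subject_scale_sd) if effects.subject_scale_sd > 0 else 1.0
    inside = brain_mask(atlas)
    maps = {}
    for name, arr in (("gm", gm), ("wm", wm), ("csf", csf), ("wmh", wmh)):
        a = arr * scale
        if effects.noise_sd > 0:
            a = a + rng.normal(0.0, effects.noise_sd, arr.shape) * inside
        maps[name] = np.clip(a, 0.0, 1.0)
    total = maps["gm"] + maps["wm"] + maps["csf"] + maps["wmh"]
    over = total > 1.0
    for a in maps.values():  # renormalise the rare voxels pushed past 1
        a[over] /= total[over]

    lac_rates = dict(effects.lacune_rates)
    if planted_conv:
        lac_rates = {k: v * effects.lacune_group_scale * profile.lacune_scale
                     for k, v in lac_rates.items()}
    lacunes = place_lacunes(rng, atlas, lac_rates)

    tissues = TissueSet(
        gm=Volume(maps["gm"], vs, tag), wm=Volume(maps["wm"], vs, tag),
        csf=Volume(maps["csf"], vs, tag), wmh=Volume(maps["wmh"], vs, tag),
        lacunes=Volume(lacunes, vs, tag),
    )
    from .volumetry import tissue_volume, total_volumes  # no import cycle: volumetry is leaf
    _, tiv = total_volumes(
        tissue_volume(tissues.gm, 0.2), tissue_volume(tissues.wm, 0.2),
        tissue_volume(tissues.wmh, 0.2), tissue_volume(tissues.csf, 0.2),
    )
    record.tiv_mm3 = tiv

    # planted voxel-wise rate of change (fractional volume change / year)
    rate = np.where(inside, effects.background_rate, 0.0)
    contraction = np.zeros(atlas.labels.shape)
    if planted_conv:
        rate = np.where(inside, profile.global_rate, 0.0)
        for roi in ("hippocampus-L", "hippocampus-R"):
            rate[atlas.labels == atlas.label_of(roi)] += profile.hippo_rate
        for roi, c in profile.jacobian_contraction.items():
            contraction[atlas.labels == atlas.label_of(roi)] = c
    jac = 1.0 - contraction
    if effects.jacobian_noise_sd > 0:
        jac = jac + rng.normal(0.0, effects.jacobian_noise_sd, jac.shape) * inside
    jac = np.clip(jac, 0.05, None)  # Jacobian determinants stay positive
    jacobian = Volume(jac, vs, tag)
    true_rate = Volume(rate, vs, tag)

    divergence: list[tuple[float, Volume]] = []
    if longitudinal:
        times = np.asarray(record.scan_times)
        t_mid = times.mean()  # registration to the average mid-point anatomy
        for t in times:
            d = rate * (t - t_mid)
            if effects.divergence_noise_sd > 0:
                d = d + rng.normal(0.0, effects.divergence_noise_sd, d.shape) * inside
            divergence.append((float(t), Volume(d, vs, tag)))

    return SyntheticSubject(
        record=record, planted_group=group,
        true_subtype=subtype if planted_conv else None,
        tissues=tissues, jacobian=jacobian, true_rate_map=true_rate,
        divergence_series=divergence,
    )


def simulate_cohort(effects: EffectSpec, seed: int,
                    atlas: Atlas | None = None,
                    imaging: bool = True,
                    longitudinal: bool = True,
                    ) -> tuple[CohortTable, list[SyntheticSubject]]:
    """Simulate a full cohort (default 97 planted non-convertors + 22 planted
    convertors, the study's group sizes).

    ``imaging=False`` skips volume generation (records only), and
    ``longitudinal=False`` skips the divergence-map series; both exist so
    that large replication studies of non-imaging properties stay cheap.
    """
    effects.validate()
    if atlas is None:
        atlas = make_atlas()
    template = make_template(atlas) if imaging else None
    rng = np.random.default_rng(seed)
    plan = [("non-convertor", None)] * effects.n_non
    # planted convertors cycle through the four subtypes
    plan += [("preVaD", 1 + i % len(effects.subtype_profiles)) for i in range(effects.n_conv)]
    subjects: list[SyntheticSubject] = []
    for i, (group, subtype) in enumerate(plan):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sid = f"s{i:03d}"
        if imaging:
            subjects.append(simulate_subject(atlas, effects, group, subtype, sub_seed,
                                             template=template, subject_id=sid,
                                             longitudinal=longitudinal))
        else:
            sub_rng = np.random.default_rng(sub_seed)
            profile = effects.subtype_profiles[subtype - 1] if subtype else None
            record = _simulate_record(sub_rng, sid, group == "preVaD", profile, effects)
            record.tiv_mm3 = 1.4e6
            subjects.append(SyntheticSubject(
                record=record, planted_group=group,
                true_subtype=subtype if group == "preVaD" else None,
                tissues=None, jacobian=None, true_rate_map=None,
                divergence_series=[],
            ))
    table = CohortTable([s.record for s in subjects])
    return table, subjects
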