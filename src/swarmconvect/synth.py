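"""Synthetic-data generators for the analysis pipeline.

Everything the analysis tools consume can be generated here: Brownian and
ballistic trajectories (ground truth for the MSD estimator), passive
tracers advected through solver output (the tracer-particle experiments),
and rendered grayscale image sequences emulating the microscopy recordings
(Gaussian spots, background, additive noise).  All generators are
deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import ImageSequence, TrajectorySet
from .sideview import StateSeries, _velocities  # noqa: F401  (velocities via states)

__all__ = [
    "RenderSpec",
    "brownian_trajectories",
    "ballistic_trajectories",
    "advect_tracers",
    "render_frames",
    "shifted_pair",
]


@dataclass(frozen=True)
class RenderSpec:
    """Rendering parameters for synthetic microscopy frames."""

    height: int = 128
    width: int = 128
    spot_sigma: float = 2.0      # Gaussian spot radius in px
    peak_intensity: float = 100.0
    background: float = 10.0
    noise_sigma: float = 0.0     # additive Gaussian noise, clipped at 0
    px_size: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0 or self.spot_sigma <= 0:
            raise ValueError("sizes must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


def brownian_trajectories(D: float, dt: float, n_steps: int, n_particles: int,
                          seed: int = 0,
                          origin_span: float = 0.0) -> TrajectorySet:
    """2D Brownian tracks with per-axis increment variance 2 D dt.

    The ensemble satisfies MSD(lag) = 4 D lag in expectation.  Starting
    positions are spread uniformly over [0, origin_span]^2 (all at the
    origin when 0).
    """
    if D < 0:
        raise ValueError("D must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = np.random.default_rng(seed)
    if origin_span > 0:
        start = rng.uniform(0.0, origin_span, size=(n_particles, 2))
    else:
        start = np.zeros((n_particles, 2))
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt),
                       size=(n_particles, n_steps, 2))
    pos = np.concatenate([start[:, None, :],
                          start[:, None, :] + np.cumsum(steps, axis=1)], axis=1)
    return _positions_to_set(pos, dt)


def ballistic_trajectories(velocity: tuple[float, float], dt: float,
                           n_steps: int, n_particles: int = 1,
                           origin_span: float = 0.0,
                           seed: int = 0) -> TrajectorySet:
    """Straight-line tracks x = x0 + v t (MSD = |v|^2 t^2)."""
    rng = np.random.default_rng(seed)
    if origin_span > 0:
        start = rng.uniform(0.0, origin_span, size=(n_particles, 2))
    else:
        start = np.zeros((n_particles, 2))
    t = np.arange(n_steps + 1) * dt
    v = np.asarray(velocity, dtype=float)
    pos = start[:, None, :] + t[None, :, None] * v[None, None, :]
    return _positions_to_set(pos, dt)


def _positions_to_set(pos: np.ndarray, dt: float) -> TrajectorySet:
    n_particles, n_times, _ = pos.shape
    t = np.arange(n_times) * dt
    table = pd.DataFrame({
        "id": np.repeat(np.arange(n_particles), n_times),
        "time": np.tile(t, n_particles),
        "x": pos[:, :, 0].ravel(),
        "y": pos[:, :, 1].ravel(),
    })
    return TrajectorySet(table=table)


# ---------------------------------------------------------------------------
# tracer advection through solver output

def _interp_velocity(state, params, x, z):
    """Bilinear velocity interpolation, periodic in x, clamped in z."""
    dx, dz = params.dx, params.dz
    fx = (x / dx) % params.Nx
    i0 = np.floor(fx).astype(int) % params.Nx
    i1 = (i0 + 1) % params.Nx
    ax = fx - np.floor(fx)
    fz = np.clip(z / dz, 0.0, params.Nz - 1 - 1e-12)
    j0 = np.floor(fz).astype(int)
    j1 = np.minimum(j0 + 1, params.Nz - 1)
    az = fz - j0

    def bilin(f):
        return ((1 - ax) * (1 - az) * f[i0, j0] + ax * (1 - az) * f[i1, j0]
                + (1 - ax) * az * f[i0, j1] + ax * az * f[i1, j1])

    return bilin(state.vx), bilin(state.vz)


def advect_tracers(series: StateSeries, starts: np.ndarray,
                   dt_sub: float = 0.01) -> TrajectorySet:
    """Integrate passive tracers through the time-interpolated flow field.

    Bilinear in space, linear in time between snapshots, midpoint (RK2) in
    time.  Tracers wrap periodically in x and reflect off the z walls, so
    none ever leaves the chamber.
    """
    params = series.params
    starts = np.asarray(starts, dtype=float)
    if starts.ndim != 2 or starts.shape[1] != 2:
        raise ValueError("starts must be (n, 2) [x, z]")
    if np.any(starts[:, 0] < 0) or np.any(starts[:, 0] > params.Lx) or \
            np.any(starts[:, 1] < 0) or np.any(starts[:, 1] > params.Lz):
        raise ValueError("tracer start outside the domain")
    times = series.times
    x = starts[:, 0].copy()
    z = starts[:, 1].copy()
    out_t = [times[0]]
    out_xy = [np.stack([x, z], axis=1)]

    def velocity_at(tq, xq, zq):
        k = int(np.clip(np.searchsorted(times, tq, side="right") - 1,
                        0, len(times) - 2))
        w = (tq - times[k]) / (times[k + 1] - times[k])
        u0, w0 = _interp_velocity(series[k], params, xq, zq)
        u1, w1 = _interp_velocity(series[k + 1], params, xq, zq)
        return (1 - w) * u0 + w * u1, (1 - w) * w0 + w * w1

    t = times[0]
    t_end = times[-1]
    while t < t_end - 1e-12:
        h = min(dt_sub, t_end - t)
        u, w = velocity_at(t, x, z)
        xm = x + 0.5 * h * u
        zm = z + 0.5 * h * w
        zm = np.clip(zm, 0.0, params.Lz)
        um, wm = velocity_at(t + 0.5 * h, xm, zm)
        x = (x + h * um) % params.Lx
        z = z + h * wm
        # reflective walls
        z = np.where(z < 0.0, -z, z)
        z = np.where(z > params.Lz, 2.0 * params.Lz - z, z)
        z = np.clip(z, 0.0, params.Lz)
        t += h
        out_t.append(t)
        out_xy.append(np.stack([x, z], axis=1))
    pos = np.stack(out_xy, axis=1)          # (n, n_times, 2)
    n, n_times, _ = pos.shape
    table = pd.DataFrame({
        "id": np.repeat(np.arange(n), n_times),
        "time": np.tile(np.asarray(out_t), n),
        "x": pos[:, :, 0].ravel(),
        "y": pos[:, :, 1].ravel(),
    })
    return TrajectorySet(table=table, units="dimensionless")


def signed_loop_area(traj: TrajectorySet, track_id) -> float:
    """Signed area swept by one track; positive = counterclockwise.

    Shoelace sum in coordinates relative to the track start, so open arcs
    are measured consistently (translation-invariant) and a mirrored track
    yields the negated area.
    """
    xy = traj.positions(track_id)
    x = xy[:, 0] - xy[0, 0]
    y = xy[:, 1] - xy[0, 1]
    return 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))


# ---------------------------------------------------------------------------
# rendering

def render_frames(traj: TrajectorySet, spec: RenderSpec,
                  fps: float) -> ImageSequence:
    """Render trajectories as Gaussian spots over a noisy background.

    Positions are interpreted in pixel units, x along columns and y along
    rows (row 0 at top).  An empty trajectory set yields background-only
    frames.
    """
    times = np.sort(traj.table["time"].unique()) if len(traj.table) else \
        np.array([0.0])
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)
    half = int(np.ceil(4.0 * spec.spot_sigma))   # truncated Gaussian stamp
    rr = np.arange(-half, half + 1)[:, None]
    cc = np.arange(-half, half + 1)[None, :]
    frames = np.zeros((len(times), h, w))
    for k, t in enumerate(times):
        img = np.full((h, w), float(spec.background))
        pts = traj.table[np.isclose(traj.table["time"], t)]
        for x, y in pts[["x", "y"]].to_numpy():
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError("particle outside the image bounds")
            ic, jc = int(round(y)), int(round(x))
            stamp = spec.peak_intensity * np.exp(
                -((cc + jc - x) ** 2 + (rr + ic - y) ** 2)
                / (2.0 * spec.spot_sigma ** 2))
            r0, r1 = max(ic - half, 0), min(ic + half + 1, h)
            c0, c1 = max(jc - half, 0), min(jc + half + 1, w)
            img[r0:r1, c0:c1] += stamp[r0 - (ic - half):
                                       stamp.shape[0] - ((ic + half + 1) - r1),
                                       c0 - (jc - half):
                                       stamp.shape[1] - ((jc + half + 1) - c1)]
        if spec.noise_sigma > 0:
            img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
        frames[k] = np.clip(img, 0.0, None)
    return ImageSequence(frames=frames, fps=fps, px_size=spec.px_size)


def closed_loop_piv_correlation(state, params, dt_frame: float | None = None,
                                px_per_unit: float = 3.2,
                                tracer_spacing: float = 1.5,
                                window: int = 32, overlap: int = 16,
                                seed: int = 0) -> dict:
    """Close the synthetic pipeline: flow -> tracers -> frames -> PIV.

    Freezes one solver snapshot, advects a dense tracer lattice through it
    for one frame interval, renders both instants as microscopy-like images
    and runs PIV on the pair.  Returns the Pearson correlation between the
    recovered displacement field and the generating velocity field sampled
    at the interrogation-window centres, plus the fields themselves.
    """
    from .analysis import piv_pair
    from .sideview import StateSeries

    if dt_frame is None:
        vmax = max(np.abs(state.vx).max(), np.abs(state.vz).max(), 1e-9)
        dt_frame = (window / 4.0) / (px_per_unit * vmax)
    frozen = StateSeries(states=[state, state.copy()], params=params)
    frozen.states[0].t = 0.0
    frozen.states[1].t = dt_frame
    margin = tracer_spacing
    xs = np.arange(margin, params.Lx - margin, tracer_spacing)
    zs = np.arange(margin, params.Lz - margin, tracer_spacing)
    starts = np.stack(np.meshgrid(xs, zs, indexing="ij"),
                      axis=-1).reshape(-1, 2)
    # jitter breaks the lattice regularity that aliases the correlation
    rng = np.random.default_rng(seed)
    starts = starts + rng.uniform(-0.4, 0.4, size=starts.shape) \
        * tracer_spacing
    starts[:, 0] = np.clip(starts[:, 0], 0, params.Lx)
    starts[:, 1] = np.clip(starts[:, 1], 0, params.Lz)
    traj = advect_tracers(frozen, starts, dt_sub=dt_frame / 4.0)
    # physical (x, z) -> image pixels, row 0 at the top of the chamber
    h = int(np.ceil(params.Lz * px_per_unit)) + 1
    w = int(np.ceil(params.Lx * px_per_unit))
    table = traj.table.copy()
    table = table[np.isclose(table["time"], 0.0)
                  | np.isclose(table["time"], dt_frame)]
    px_x = table["x"] * px_per_unit
    px_y = (params.Lz - table["y"]) * px_per_unit
    keep = (px_x < w - 1) & (px_y < h - 1) & (px_x >= 0) & (px_y >= 0)
    table = table.assign(x=px_x, y=px_y)[keep]
    from .analysis import TrajectorySet as _TS
    import pandas as _pd
    # re-key tracks that lost an endpoint so each id has both frames
    counts = table.groupby("id")["time"].count()
    table = table[table["id"].isin(counts[counts == 2].index)]
    traj_px = _TS(table=_pd.DataFrame(table))
    spec = RenderSpec(height=h, width=w, spot_sigma=1.5,
                      peak_intensity=100.0, background=5.0,
                      noise_sigma=1.0, seed=seed)
    seq = render_frames(traj_px, spec, fps=1.0 / dt_frame)
    fieldv = piv_pair(seq.frames[0], seq.frames[1],
                      window=window, overlap=overlap)
    # generating field at the window centres
    xc = fieldv.x[None, :].repeat(fieldv.y.size, axis=0)
    yc = fieldv.y[:, None].repeat(fieldv.x.size, axis=1)
    phys_x = xc.ravel() / px_per_unit
    phys_z = params.Lz - yc.ravel() / px_per_unit
    vx_ref, vz_ref = _interp_velocity(state, params, phys_x, phys_z)
    u_ref = (vx_ref * px_per_unit * dt_frame).reshape(fieldv.u.shape)
    v_ref = (-vz_ref * px_per_unit * dt_frame).reshape(fieldv.v.shape)
    m = fieldv.mask
    a = np.concatenate([fieldv.u[m], fieldv.v[m]])
    b = np.concatenate([u_ref[m], v_ref[m]])
    corr = float(np.corrcoef(a, b)[0, 1])
    return {"correlation": corr, "piv": fieldv,
            "u_ref": u_ref, "v_ref": v_ref, "dt_frame": dt_frame,
            "n_valid": int(m.sum())}


def shifted_pair(image: np.ndarray, dx: float, dy: float):
    """Return (image, image shifted by (dx, dy)) with periodic wrap.

    Integer shifts use roll; subpixel shifts use the Fourier shift theorem,
    so shifting by (dx, dy) and then (-dx, -dy) restores the original to
    round-off.  dx moves content along columns (x), dy along rows.
    """
    img = np.asarray(image, dtype=float)
    if abs(dx) >= img.shape[1] or abs(dy) >= img.shape[0]:
        raise ValueError("shift exceeds the image size")
    if float(dx).is_integer() and float(dy).is_integer():
        shifted = np.roll(np.roll(img, int(dy), axis=0), int(dx), axis=1)
    else:
        ky = np.fft.fftfreq(img.shape[0])[:, None]
        kx = np.fft.fftfreq(img.shape[1])[None, :]
        phase = np.exp(-2j * np.pi * (kx * dx + ky * dy))
        shifted = np.real(np.fft.ifft2(np.fft.fft2(img) * phase))
    return img, shifted
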