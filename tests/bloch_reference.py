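"""Independent fine-step Bloch integrator used as a test oracle.

Deliberately simple and structurally different from the package's
propagator: within each RF pulse the Hanning envelope and the gradient field
are integrated with a uniform fine time step (default 10 us, aligned to the
pulse boundaries), rotating the magnetisation about the instantaneous
effective field at every step; between pulses the field is constant (gradient
only) and a single exact rotation covers the gap.  No sub-pulse collapsing,
no off-resonance culling, no early termination.
"""

import numpy as np

from mpasl.bloch import GAMMA, PulseTrainParams, path_half_length


def _rotate(m, ox, oy, oz, dt):
    """Rodrigues rotation of m (K,3) about the field (ox,oy,oz) for time dt."""
    omega = np.stack([np.broadcast_to(ox, oz.shape),
                      np.broadcast_to(oy, oz.shape),
                      oz], axis=1)
    norm = np.linalg.norm(omega, axis=1)
    ang = norm * dt
    axis = np.where(norm[:, None] > 0, omega / np.where(norm[:, None] > 0, norm[:, None], 1.0), 0.0)
    c = np.cos(ang)[:, None]
    s = np.sin(ang)[:, None]
    dot = (axis * m).sum(axis=1, keepdims=True)
    cross = np.cross(axis, m)
    return m * c + cross * s + axis * dot * (1.0 - c)


def reference_spin_profile(pulses: PulseTrainParams, laminar_velocity: float,
                           phase_offsets, dt_step: float = 10e-6) -> np.ndarray:
    """Final Mz per phase offset (radians) from brute-force integration."""
    dpsi = np.atleast_1d(np.asarray(phase_offsets, dtype=float))
    K = dpsi.size

    v = laminar_velocity / 100.0
    dt = pulses.pulse_interval * 1e-6
    tau = pulses.pulse_width * 1e-6
    g_label = pulses.label_gradient * 1e-3
    g_rest = (pulses.mean_gradient * 1e-3 * dt - g_label * tau) / (dt - tau)
    flip = np.deg2rad(pulses.flip_angle)
    t2 = pulses.t2_blood * 1e-3
    half_len = path_half_length(pulses)

    n_pulses = int(np.ceil(2.0 * half_len / (v * dt)))
    n_in = int(np.ceil(tau / dt_step))
    dt_in = tau / n_in

    m = np.zeros((K, 3))
    m[:, 2] = 1.0
    for n in range(n_pulses):
        t0 = n * dt
        psi = n * dpsi
        cpsi, spsi = np.cos(psi), np.sin(psi)
        # pulse window: fine steps, Hanning envelope sampled mid-step
        for i in range(n_in):
            t_mid = (i + 0.5) * dt_in
            z = -half_len + v * (t0 + t_mid)
            w1 = (flip / tau) * (1.0 - np.cos(2.0 * np.pi * t_mid / tau))
            m = _rotate(m, w1 * cpsi, w1 * spsi,
                        np.full(K, GAMMA * g_label * z), dt_in)
            decay = np.exp(-dt_in / t2)
            m[:, 0] *= decay
            m[:, 1] *= decay
        # gap: constant gradient field, one exact rotation about z
        z_mid = -half_len + v * (t0 + tau + 0.5 * (dt - tau))
        ang = GAMMA * g_rest * z_mid * (dt - tau)
        c, s = np.cos(ang), np.sin(ang)
        mx = c * m[:, 0] - s * m[:, 1]
        my = s * m[:, 0] + c * m[:, 1]
        decay = np.exp(-(dt - tau) / t2)
        m[:, 0] = mx * decay
        m[:, 1] = my * decay
    return m[:, 2]
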