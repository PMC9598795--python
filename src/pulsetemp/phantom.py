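"""Coupled electro-thermal simulation of the agar ablation phantom.

Quasi-static electric field with temperature-dependent conductivity,
duty-cycled Joule heating, and transient heat conduction with convective
exterior boundaries, discretized by node-centered finite volumes on an
axisymmetric (r, z) mesh.

The electric problem is linear in the applied voltage, so the potential
is solved once per conductivity refresh in normalized form (electrode at
1, ground at 0) and scaled; impedance and Joule power follow from the
same discrete fluxes, which makes the dissipated power equal V*I and the
adiabatic energy balance exact at the discrete level.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import (AGAR, INSULATION, STAINLESS_STEEL, MaterialProperties,
                       NumericsConfig, PhantomGeometry, ProbeGeometry,
                       TreatmentCondition, update_conductivity)
from .mesh import (AGAR_NODE, ELECTRODE_ACTIVE, ELECTRODE_GROUND,
                   INSULATOR_NODE, AxiMesh, build_phantom_mesh)

__all__ = ["FieldState", "TreatmentTrace", "ElectricalSystem",
           "ThermalSystem", "solve_potential", "electric_field",
           "joule_source", "phantom_resistance", "step_temperature",
           "run_treatment", "default_materials"]

TRACE_COLUMNS = ("time_s", "T4_C", "T10_C", "Z_ohm", "dZ_ohm")


def default_materials(sigma_ref: float = AGAR.electrical_conductivity,
                      ) -> dict[int, MaterialProperties]:
    """Material assignment per mesh label, with the agar conductivity
    quoted at 37 degC."""
    agar = replace(AGAR, electrical_conductivity=sigma_ref)
    return {AGAR_NODE: agar, INSULATOR_NODE: INSULATION,
            ELECTRODE_ACTIVE: STAINLESS_STEEL,
            ELECTRODE_GROUND: STAINLESS_STEEL}


@dataclass
class FieldState:
    """Snapshot of the solver fields on the mesh (grids of shape nr x nz)."""

    potential: np.ndarray       # V
    temperature: np.ndarray     # degC
    conductivity: np.ndarray    # S/m
    heat_source: np.ndarray     # W/m^3, duty-cycle averaged


@dataclass
class TreatmentTrace:
    """1 Hz record of one treatment run.

    ``T4``/``T10`` are absolute sensor temperatures (degC), ``Z`` the
    low-frequency phantom impedance (ohm) and ``dZ = Z(t) - Z(0)``
    (negative under heating).
    """

    time: np.ndarray
    T4: np.ndarray
    T10: np.ndarray
    Z: np.ndarray
    condition: str = ""
    deposited_energy: float = 0.0  # J, time-integrated Joule power

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.T4) == len(self.T10) == len(self.Z) == n):
            raise ValueError("trace channels must have equal length")
        if np.any(self.Z <= 0):
            raise ValueError("impedance must be positive")

    @property
    def dZ(self) -> np.ndarray:
        return self.Z - self.Z[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "T4_C": self.T4,
                             "T10_C": self.T10, "Z_ohm": self.Z,
                             "dZ_ohm": self.dZ})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, condition: str = "") -> "TreatmentTrace":
        df = pd.read_csv(path)
        missing = set(TRACE_COLUMNS[:4]) - set(df.columns)
        if missing:
            raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
        return cls(time=df["time_s"].to_numpy(float),
                   T4=df["T4_C"].to_numpy(float),
                   T10=df["T10_C"].to_numpy(float),
                   Z=df["Z_ohm"].to_numpy(float), condition=condition)


class ElectricalSystem:
    """Discrete conduction problem -div(sigma grad phi) = 0 on one mesh.

    Unknowns are the agar nodes; electrode nodes are Dirichlet (1 / 0 in
    normalized form); insulator surfaces and the domain exterior carry
    zero normal current.
    """

    def __init__(self, mesh: AxiMesh):
        self.mesh = mesh
        nr, nz = mesh.shape
        labels = mesh.labels
        flat = labels.reshape(-1)
        self.agar_flat = np.flatnonzero(flat == AGAR_NODE)
        if not (np.any(flat == ELECTRODE_ACTIVE)
                and np.any(flat == ELECTRODE_GROUND)):
            raise ValueError("mesh must label both electrodes")
        unk = -np.ones(nr * nz, dtype=np.int64)
        unk[self.agar_flat] = np.arange(len(self.agar_flat))
        self.n_unk = len(self.agar_flat)

        int_a, int_b, int_gf = [], [], []
        bnd_p, bnd_node, bnd_gf, bnd_val, bnd_kind = [], [], [], [], []

        def add_face(pa, pb, gf, face_label):
            la, lb = flat[pa], flat[pb]
            if face_label != AGAR_NODE:
                return
            if la == INSULATOR_NODE or lb == INSULATOR_NODE:
                return
            if la == AGAR_NODE and lb == AGAR_NODE:
                int_a.append(pa); int_b.append(pb); int_gf.append(gf)
            elif la == AGAR_NODE or lb == AGAR_NODE:
                agar, elec = (pa, pb) if la == AGAR_NODE else (pb, pa)
                kind = flat[elec]
                bnd_p.append(unk[agar]); bnd_node.append(agar)
                bnd_gf.append(gf); bnd_kind.append(kind)
                bnd_val.append(1.0 if kind == ELECTRODE_ACTIVE else 0.0)

        for i in range(nr - 1):
            for j in range(nz):
                add_face(i * nz + j, (i + 1) * nz + j,
                         mesh.area_r[i, j] / mesh.dr[i],
                         mesh.face_label_r[i, j])
        for i in range(nr):
            for j in range(nz - 1):
                add_face(i * nz + j, i * nz + j + 1,
                         mesh.area_z[i, j] / mesh.dz[j],
                         mesh.face_label_z[i, j])

        self.int_a = np.asarray(int_a, dtype=np.int64)
        self.int_b = np.asarray(int_b, dtype=np.int64)
        self.int_gf = np.asarray(int_gf)
        self.int_ua = unk[self.int_a]
        self.int_ub = unk[self.int_b]
        self.bnd_p = np.asarray(bnd_p, dtype=np.int64)
        self.bnd_node = np.asarray(bnd_node, dtype=np.int64)
        self.bnd_gf = np.asarray(bnd_gf)
        self.bnd_val = np.asarray(bnd_val)
        self.bnd_kind = np.asarray(bnd_kind)
        self._unk = unk
        # insulator fill: nearest non-insulator node at larger radius,
        # used only to report a bounded potential inside the probe body
        fill_src = {}
        for i in range(nr):
            for j in range(nz):
                if labels[i, j] == INSULATOR_NODE:
                    for i2 in range(i + 1, nr):
                        if labels[i2, j] != INSULATOR_NODE:
                            fill_src[i * nz + j] = i2 * nz + j
                            break
        self._fill_dst = np.asarray(list(fill_src.keys()), dtype=np.int64)
        self._fill_src = np.asarray(list(fill_src.values()), dtype=np.int64)

    # -- face conductances ------------------------------------------------
    def _face_G(self, sigma_flat: np.ndarray):
        sa = sigma_flat[self.int_a]
        sb = sigma_flat[self.int_b]
        g_int = self.int_gf * (2.0 * sa * sb / (sa + sb))
        g_bnd = self.bnd_gf * sigma_flat[self.bnd_node]
        return g_int, g_bnd

    def solve_normalized(self, sigma_field: np.ndarray) -> np.ndarray:
        """Potential grid for unit applied voltage (active=1, ground=0)."""
        sigma_flat = np.asarray(sigma_field, dtype=float).reshape(-1)
        if np.any(sigma_flat[self.agar_flat] <= 0):
            raise ValueError("conductivity must be positive in the agar")
        g_int, g_bnd = self._face_G(sigma_flat)
        n = self.n_unk
        rows = np.concatenate([self.int_ua, self.int_ub,
                               self.int_ua, self.int_ub, self.bnd_p])
        cols = np.concatenate([self.int_ua, self.int_ub,
                               self.int_ub, self.int_ua, self.bnd_p])
        vals = np.concatenate([g_int, g_int, -g_int, -g_int, g_bnd])
        A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
        rhs = np.zeros(n)
        np.add.at(rhs, self.bnd_p, g_bnd * self.bnd_val)
        sol = splu(A).solve(rhs)
        phi = np.zeros(self.mesh.n_nodes)
        phi[self.agar_flat] = sol
        flat_labels = self.mesh.labels.reshape(-1)
        phi[flat_labels == ELECTRODE_ACTIVE] = 1.0
        phi[flat_labels == ELECTRODE_GROUND] = 0.0
        if len(self._fill_dst):
            phi[self._fill_dst] = phi[self._fill_src]
        return phi.reshape(self.mesh.shape)

    def conductance(self, sigma_field: np.ndarray,
                    phi_hat: np.ndarray) -> float:
        """Total conductance (S) from the dissipation functional.

        Exact (equal to I/V) when ``phi_hat`` solves the current sigma
        field; a second-order accurate variational estimate when sigma
        has drifted since the last solve."""
        sigma_flat = np.asarray(sigma_field, float).reshape(-1)
        phi = np.asarray(phi_hat, float).reshape(-1)
        g_int, g_bnd = self._face_G(sigma_flat)
        d_int = phi[self.int_a] - phi[self.int_b]
        d_bnd = self.bnd_val - phi[self.bnd_node]
        return float(np.sum(g_int * d_int ** 2) + np.sum(g_bnd * d_bnd ** 2))

    def electrode_current(self, sigma_field: np.ndarray,
                          phi_hat: np.ndarray, electrode: str = "active",
                          voltage: float = 1.0) -> float:
        """Total current (A) through one electrode surface."""
        sigma_flat = np.asarray(sigma_field, float).reshape(-1)
        phi = np.asarray(phi_hat, float).reshape(-1)
        _, g_bnd = self._face_G(sigma_flat)
        kind = ELECTRODE_ACTIVE if electrode == "active" else ELECTRODE_GROUND
        m = self.bnd_kind == kind
        if electrode == "active":
            i_hat = np.sum(g_bnd[m] * (1.0 - phi[self.bnd_node[m]]))
        else:
            i_hat = np.sum(g_bnd[m] * phi[self.bnd_node[m]])
        return float(voltage * i_hat)

    def node_power(self, sigma_field: np.ndarray,
                   phi_hat: np.ndarray) -> np.ndarray:
        """Normalized dissipated power per node (W at 1 V applied).

        Face dissipation G*(dphi)^2 is shared between adjacent agar nodes
        (entirely to the agar node on electrode faces), so the grid sums
        exactly to the total conductance."""
        sigma_flat = np.asarray(sigma_field, float).reshape(-1)
        phi = np.asarray(phi_hat, float).reshape(-1)
        g_int, g_bnd = self._face_G(sigma_flat)
        p_face = g_int * (phi[self.int_a] - phi[self.int_b]) ** 2
        p = np.zeros(self.mesh.n_nodes)
        np.add.at(p, self.int_a, 0.5 * p_face)
        np.add.at(p, self.int_b, 0.5 * p_face)
        np.add.at(p, self.bnd_node,
                  g_bnd * (self.bnd_val - phi[self.bnd_node]) ** 2)
        return p.reshape(self.mesh.shape)


def _electrical(mesh: AxiMesh) -> ElectricalSystem:
    sys_ = getattr(mesh, "_elec_system", None)
    if sys_ is None:
        sys_ = ElectricalSystem(mesh)
        mesh._elec_system = sys_
    return sys_


def solve_potential(mesh: AxiMesh, sigma_field: np.ndarray,
                    voltage: float) -> np.ndarray:
    """Solve -div(sigma grad phi) = 0 with the active electrode at
    ``voltage`` and the ground electrode at 0; exterior and insulator
    boundaries carry zero normal current.  Returns the potential grid."""
    return voltage * _electrical(mesh).solve_normalized(sigma_field)


def electric_field(phi: np.ndarray, mesh: AxiMesh) -> np.ndarray:
    """|E| = |-grad(phi)| by central differences on the tensor grid."""
    phi = np.asarray(phi, dtype=float)
    if phi.shape != mesh.shape:
        raise ValueError("potential grid does not match mesh")
    er = -np.gradient(phi, mesh.r, axis=0)
    ez = -np.gradient(phi, mesh.z, axis=1)
    return np.hypot(er, ez)


def joule_source(sigma_field: np.ndarray, e_mag: np.ndarray,
                 burst_on_time: float, burst_period: float) -> np.ndarray:
    """Duty-cycled Joule heating density QJ = sigma * |E|^2 * p / tau."""
    if not 0 < burst_on_time <= burst_period:
        raise ValueError("require 0 < burst_on_time <= burst_period")
    sigma = np.asarray(sigma_field, dtype=float)
    e = np.asarray(e_mag, dtype=float)
    return sigma * e ** 2 * (burst_on_time / burst_period)


def phantom_resistance(phi: np.ndarray, sigma_field: np.ndarray,
                       mesh: AxiMesh, voltage: float,
                       electrode: str = "active") -> float:
    """Resistance V/I with I integrated over one electrode surface."""
    if voltage <= 0:
        raise ValueError("voltage must be positive for resistance")
    phi_hat = np.asarray(phi, dtype=float) / voltage
    current = _electrical(mesh).electrode_current(
        sigma_field, phi_hat, electrode=electrode, voltage=voltage)
    if current <= 0:
        raise ValueError("non-positive electrode current; check labeling")
    return voltage / current


class ThermalSystem:
    """Implicit-Euler heat conduction with convective exterior boundaries.

    rho*cp dT/dt = div(k grad T) + Q, with -k dT/dn = h (T - Text) on the
    sides listed in ``mesh.convective``.  The operator is constant, so it
    is factorized once and each step is a pair of triangular solves."""

    def __init__(self, mesh: AxiMesh,
                 materials: dict[int, MaterialProperties],
                 phantom: PhantomGeometry, dt: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.mesh, self.dt = mesh, dt
        self.text = phantom.ambient_temperature
        nr, nz = mesh.shape
        n = nr * nz
        rho_cp = np.empty(n)
        for label, m in materials.items():
            rho_cp[mesh.labels.reshape(-1) == label] = m.density * m.specific_heat
        self.capacity = rho_cp * mesh.volumes.reshape(-1)  # J/K per node

        k_of = {label: m.thermal_conductivity for label, m in materials.items()}
        rows, cols, vals = [], [], []

        def add_face(pa, pb, gf, face_label):
            g = k_of[int(face_label)] * gf
            rows.extend([pa, pb, pa, pb])
            cols.extend([pa, pb, pb, pa])
            vals.extend([g, g, -g, -g])

        for i in range(nr - 1):
            for j in range(nz):
                add_face(i * nz + j, (i + 1) * nz + j,
                         mesh.area_r[i, j] / mesh.dr[i],
                         mesh.face_label_r[i, j])
        for i in range(nr):
            for j in range(nz - 1):
                add_face(i * nz + j, i * nz + j + 1,
                         mesh.area_z[i, j] / mesh.dz[j],
                         mesh.face_label_z[i, j])
        L = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

        conv = np.zeros(n)
        h = phantom.convective_coefficient
        if h > 0:
            for side in mesh.convective:
                areas = mesh.outer_area(side)
                if side == "outer":
                    idx = (nr - 1) * nz + np.arange(nz)
                elif side == "inner":
                    idx = np.arange(nz)
                elif side == "top":
                    idx = np.arange(nr) * nz + (nz - 1)
                else:  # bottom
                    idx = np.arange(nr) * nz
                conv[idx] += h * areas
        self.conv_rhs = conv * self.text
        A = sp.diags(self.capacity / dt) + L + sp.diags(conv)
        self._lu = splu(A.tocsc())

    def step(self, temperature: np.ndarray,
             node_power: np.ndarray) -> np.ndarray:
        """Advance one implicit step; ``node_power`` in W per node."""
        t_flat = np.asarray(temperature, float).reshape(-1)
        p_flat = np.asarray(node_power, float).reshape(-1)
        rhs = self.capacity / self.dt * t_flat + p_flat + self.conv_rhs
        return self._lu.solve(rhs).reshape(self.mesh.shape)


def step_temperature(mesh: AxiMesh, temperature: np.ndarray,
                     heat_source: np.ndarray, dt: float,
                     materials: dict[int, MaterialProperties],
                     phantom: PhantomGeometry) -> np.ndarray:
    """One implicit heat-conduction step with volumetric source
    ``heat_source`` (W/m^3).  Convenience wrapper over ThermalSystem."""
    system = ThermalSystem(mesh, materials, phantom, dt)
    power = np.asarray(heat_source, float) * mesh.volumes
    return system.step(temperature, power)


def run_treatment(cond: TreatmentCondition,
                  probe: ProbeGeometry | None = None,
                  phantom: PhantomGeometry | None = None,
                  numerics: NumericsConfig | None = None,
                  mesh: AxiMesh | None = None,
                  full_output: bool = False):
    """Simulate one treatment and return the 1 Hz TreatmentTrace.

    At each 1 s burst: refresh sigma(T) in the agar, re-solve the
    potential when due (every ``resolve_interval`` s or when the maximum
    temperature change since the last solve exceeds ``resolve_dtemp``),
    deposit the duty-cycled Joule power, and advance the temperature one
    implicit step.  T4/T10 are sampled by bilinear interpolation at the
    sensor radii, level with the active electrode midpoint; Z(t) = V/I is
    recorded alongside.
    """
    probe = probe or ProbeGeometry()
    phantom = phantom or PhantomGeometry()
    numerics = numerics or NumericsConfig()
    if mesh is None:
        mesh = build_phantom_mesh(probe, phantom, numerics)
    elec = _electrical(mesh)
    mats = default_materials(cond.sigma_ref)
    thermal = ThermalSystem(mesh, mats, phantom, numerics.dt)

    agar = mesh.labels == AGAR_NODE
    sigma_static = np.empty(mesh.shape)
    for label, m in mats.items():
        sigma_static[mesh.labels == label] = m.electrical_conductivity

    def sigma_of(T):
        s = sigma_static.copy()
        s[agar] = update_conductivity(T[agar], cond.sigma_ref, cond.alpha,
                                      37.0, numerics.sigma_floor)
        return s

    T = np.full(mesh.shape, float(cond.agar_temperature))
    sigma = sigma_of(T)
    phi_hat = elec.solve_normalized(sigma)
    t_ref, time_ref = T.copy(), 0.0

    duty = cond.duty_cycle
    v2 = cond.applied_voltage ** 2
    n_steps = int(round(cond.duration / numerics.dt))
    rec_every = max(1, int(round(1.0 / numerics.dt)))

    times, t4s, t10s, zs = [0.0], [], [], []
    (sr4, sr10), sz = mesh.sensor_r, mesh.sensor_z
    t4s.append(mesh.interpolate(T, sr4, sz))
    t10s.append(mesh.interpolate(T, sr10, sz))
    zs.append(1.0 / elec.conductance(sigma, phi_hat))

    energy = 0.0
    for step in range(1, n_steps + 1):
        t_now = step * numerics.dt
        if (t_now - time_ref >= numerics.resolve_interval - 1e-9
                or np.max(np.abs(T - t_ref)) > numerics.resolve_dtemp):
            phi_hat = elec.solve_normalized(sigma)
            t_ref, time_ref = T.copy(), t_now
        power = v2 * duty * elec.node_power(sigma, phi_hat)
        energy += float(power.sum()) * numerics.dt
        T = thermal.step(T, power)
        sigma = sigma_of(T)
        if step % rec_every == 0:
            times.append(t_now)
            t4s.append(mesh.interpolate(T, sr4, sz))
            t10s.append(mesh.interpolate(T, sr10, sz))
            zs.append(1.0 / elec.conductance(sigma, phi_hat))

    trace = TreatmentTrace(time=np.asarray(times), T4=np.asarray(t4s),
                           T10=np.asarray(t10s), Z=np.asarray(zs),
                           condition=cond.name, deposited_energy=energy)
    if full_output:
        qj = v2 * duty * elec.node_power(sigma, phi_hat) / mesh.volumes
        state = FieldState(potential=cond.applied_voltage * phi_hat,
                           temperature=T, conductivity=sigma, heat_source=qj)
        return trace, state
    return trace
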