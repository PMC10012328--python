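"""Two-region architecture and connectivity.

Neocortex (NC): 20 neurons in two modality subgroups (visual, auditory) of
10.  Hippocampus: 10 neurons in two matching subgroups of 5.  Within each
NC subgroup, directed pairs connect sparsely (p = 0.25, fixed weight); no
synapses cross NC subgroups.  Each NC subgroup is fully bipartitely
connected to its hippocampal counterpart (and back), fixed.  Hippocampal
directed pairs exist with p = 0.5 and are the only plastic synapses:
intra-subgroup efficacies start at maximum, inter-subgroup at zero — the
inter-subgroup weights are the memory read-out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .kernels import OscillatorState
from .params import ConnectivitySpec
from .plasticity import SynapseMatrix

__all__ = ["Architecture", "build_network", "reset_theta_phase",
           "network_to_adjacency"]


@dataclass(frozen=True)
class Architecture:
    """Index layout: NC visual, NC auditory, hip visual, hip auditory."""

    nc_per_subgroup: int = 10
    hip_per_subgroup: int = 5

    @property
    def n(self) -> int:
        return 2 * self.nc_per_subgroup + 2 * self.hip_per_subgroup

    @property
    def nc_visual(self) -> np.ndarray:
        return np.arange(0, self.nc_per_subgroup)

    @property
    def nc_auditory(self) -> np.ndarray:
        return np.arange(self.nc_per_subgroup, 2 * self.nc_per_subgroup)

    @property
    def hip_visual(self) -> np.ndarray:
        base = 2 * self.nc_per_subgroup
        return np.arange(base, base + self.hip_per_subgroup)

    @property
    def hip_auditory(self) -> np.ndarray:
        base = 2 * self.nc_per_subgroup + self.hip_per_subgroup
        return np.arange(base, base + self.hip_per_subgroup)

    @property
    def nc(self) -> np.ndarray:
        return np.arange(0, 2 * self.nc_per_subgroup)

    @property
    def hip(self) -> np.ndarray:
        base = 2 * self.nc_per_subgroup
        return np.arange(base, base + 2 * self.hip_per_subgroup)

    @property
    def hip_mask(self) -> np.ndarray:
        m = np.zeros(self.n, dtype=bool)
        m[self.hip] = True
        return m

    def subgroup(self, region: str, modality: str) -> np.ndarray:
        return getattr(self, f"{region}_{modality}")

    def labels(self) -> List[Tuple[str, str]]:
        """(region, subgroup) label per neuron index."""
        out = []
        for idx in range(self.n):
            if idx in self.nc_visual:
                out.append(("nc", "visual"))
            elif idx in self.nc_auditory:
                out.append(("nc", "auditory"))
            elif idx in self.hip_visual:
                out.append(("hip", "visual"))
            else:
                out.append(("hip", "auditory"))
        return out


def build_network(spec: ConnectivitySpec, rng: np.random.Generator,
                  arch: Architecture | None = None
                  ) -> Tuple[Architecture, SynapseMatrix]:
    """Draw one network realisation; a pure function of (spec, seed).

    Connection draws are independent per *directed* pair, so bidirectional
    hippocampal pairs arise with probability p^2.  No self-connections.
    """
    if rng is None:
        raise ValueError("build_network: a seeded Generator is required "
                         "(reproducibility)")
    arch = arch or Architecture()
    n = arch.n
    exists = np.zeros((n, n), dtype=bool)
    w_max = np.zeros((n, n))
    rho = np.zeros((n, n))
    plastic = np.zeros((n, n), dtype=bool)

    # NC intra-subgroup sparse fixed recurrence; none across subgroups.
    for grp in (arch.nc_visual, arch.nc_auditory):
        draws = rng.random((grp.size, grp.size)) < spec.nc_intra_p
        np.fill_diagonal(draws, False)
        for a, i in enumerate(grp):
            for b, j in enumerate(grp):
                if draws[a, b]:
                    exists[i, j] = True
                    w_max[i, j] = spec.nc_intra_wmax
                    rho[i, j] = 1.0

    # Full bipartite NC <-> hip within modality, fixed weights.
    for mod in ("visual", "auditory"):
        nc_grp = arch.subgroup("nc", mod)
        hip_grp = arch.subgroup("hip", mod)
        for i in nc_grp:
            for j in hip_grp:
                exists[i, j] = True
                w_max[i, j] = spec.nc_to_hip_wmax
                rho[i, j] = 1.0
        for i in hip_grp:
            for j in nc_grp:
                exists[i, j] = True
                w_max[i, j] = spec.hip_to_nc_wmax
                rho[i, j] = 1.0

    # Hippocampal pairs: p = 0.5 per directed pair, all plastic;
    # intra-subgroup efficacy starts at maximum, inter-subgroup at zero.
    hip = arch.hip
    draws = rng.random((hip.size, hip.size)) < spec.hip_p
    np.fill_diagonal(draws, False)
    in_vis = np.isin(hip, arch.hip_visual)
    for a, i in enumerate(hip):
        for b, j in enumerate(hip):
            if draws[a, b]:
                exists[i, j] = True
                w_max[i, j] = spec.hip_wmax
                plastic[i, j] = True
                rho[i, j] = 1.0 if in_vis[a] == in_vis[b] else 0.0

    return arch, SynapseMatrix(exists, w_max, rho, plastic)


def gated_pairs(arch: Architecture) -> np.ndarray:
    """Boolean (n, n) mask of NC->hippocampus pairs, whose EPSPs pass
    through the entorhinal gate at delivery time."""
    m = np.zeros((arch.n, arch.n), dtype=bool)
    m[np.ix_(arch.nc, arch.hip)] = True
    return m


def reset_theta_phase(osc: OscillatorState, stimulus_onset_ms: float,
                      visual_phase_offset: float = 0.0) -> OscillatorState:
    """Reset hippocampal theta at stimulus onset, 180 deg from the visual
    stimulus modulation.

    The visual drive is ``A (1 - cos(w t + phi_v)) / 2``, i.e. at its
    trough at onset when ``phi_v = 0``.  The reset pins the theta phase so
    the hippocampal cosine is in antiphase with the visual modulation:
    theta = 1 at onset (for the default trough-onset convention) and
    theta = 0 — the LTP-permissive extreme — at every visual peak.
    """
    return OscillatorState(frequency=osc.frequency,
                           phase=visual_phase_offset % (2.0 * np.pi),
                           amplitude=osc.amplitude)


def network_to_adjacency(arch: Architecture, syn: SynapseMatrix
                         ) -> List[Dict]:
    """JSON-ready adjacency listing (pre, post, w_max, rho0, plastic)."""
    labels = arch.labels()
    out = []
    for i, j in zip(*np.nonzero(syn.exists)):
        out.append({
            "pre": int(i), "post": int(j),
            "pre_group": "_".join(labels[i]), "post_group": "_".join(labels[j]),
            "w_max": float(syn.w_max[i, j]),
            "rho0": float(syn.rho[i, j]),
            "plastic": bool(syn.plastic[i, j]),
        })
    return out
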