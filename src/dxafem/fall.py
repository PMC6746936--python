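"""Sideways-fall load case on the femur plate model.

The boundary conditions mimic a fall on the greater trochanter:

* the impact force is applied over the lateral trochanteric surface, inclined
  30 degrees counter-clockwise from the axis perpendicular to the (fitted)
  shaft axis, pushing towards the femoral head;
* the femoral head is grounded through translational springs (total
  stiffness split uniformly over the head boundary nodes, isotropic
  in-plane), standing in for the acetabular contact;
* the distal cut of the shaft is rigidly linked to a pinned master node that
  can only rotate (a distal hinge).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import BoundaryConfig
from .materials import MaterialField
from .meshing import PlanarMesh
from .solver import RigidHinge, SolveResult, solve_plane_stress


@dataclass
class LoadCase:
    impact_force_n: float
    force_dir: np.ndarray               # unit vector, y-up mm frame
    load_nodes: np.ndarray
    spring_nodes: np.ndarray
    spring_k_per_node: float            # N/mm, per direction
    hinge: RigidHinge

    @property
    def force_vector(self) -> np.ndarray:
        return self.impact_force_n * self.force_dir


def _nodes_of(mesh: PlanarMesh, element_sel: np.ndarray) -> np.ndarray:
    return np.unique(mesh.elements[element_sel])


def build_load_case(
    mesh: PlanarMesh,
    head_elements: np.ndarray,
    troch_elements: np.ndarray,
    shaft_up: np.ndarray,
    impact_force_n: float,
    cfg: BoundaryConfig = BoundaryConfig(),
) -> LoadCase:
    """Derive node sets and the force direction for the fall simulation."""
    if impact_force_n <= 0:
        raise ValueError("impact force must be > 0")
    boundary = mesh.boundary_nodes()

    head_nodes = np.intersect1d(boundary, _nodes_of(mesh, head_elements))
    if head_nodes.size == 0:
        raise ValueError("no head boundary nodes: cannot place the springs")

    troch_nodes = np.intersect1d(boundary, _nodes_of(mesh, troch_elements))
    if troch_nodes.size == 0:
        raise ValueError("no trochanteric boundary nodes: cannot load")
    # lateral side of the trochanter: opposite the medial direction,
    # relative to the trochanteric node centroid
    sign = 1.0 if cfg.medial_direction == "+x" else -1.0
    xc = mesh.nodes[troch_nodes, 0].mean()
    lateral = troch_nodes[sign * (mesh.nodes[troch_nodes, 0] - xc) <= 0.0]
    if lateral.size == 0:
        lateral = troch_nodes
    # arc fraction: keep the most lateral nodes
    n_keep = max(1, int(round(cfg.troch_arc_fraction * lateral.size)))
    order = np.argsort(sign * mesh.nodes[lateral, 0])
    load_nodes = np.sort(lateral[order[:n_keep]])

    # force direction: rotate the medial in-plane perpendicular of the shaft
    # axis by the configured angle (counter-clockwise on a medial=+x scan,
    # mirrored otherwise)
    up = shaft_up / np.linalg.norm(shaft_up)
    medial_perp = sign * np.array([up[1], -up[0]])
    if medial_perp[0] * sign < 0:
        medial_perp = -medial_perp
    ang = math.radians(cfg.force_angle_deg) * sign
    rot = np.array(
        [[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]]
    )
    force_dir = rot @ medial_perp

    # distal edge: the bottom row of nodes of the mesh
    y_min = mesh.nodes[:, 1].min()
    distal = np.nonzero(np.isclose(mesh.nodes[:, 1], y_min))[0]
    if distal.size < 2:
        raise ValueError("distal edge too small for a hinge")
    master = np.array([mesh.nodes[distal, 0].mean(), y_min])

    return LoadCase(
        impact_force_n=float(impact_force_n),
        force_dir=force_dir,
        load_nodes=load_nodes,
        spring_nodes=head_nodes,
        spring_k_per_node=cfg.head_spring_total_n_per_mm / head_nodes.size,
        hinge=RigidHinge(slave_nodes=distal, master_xy=master),
    )


def solve_fall(
    mesh: PlanarMesh, materials: MaterialField, load: LoadCase
) -> SolveResult:
    """Run the plane-stress solve for one patient's fall load case."""
    f = np.zeros(2 * mesh.n_nodes)
    per_node = load.force_vector / load.load_nodes.size
    f[2 * load.load_nodes] = per_node[0]
    f[2 * load.load_nodes + 1] = per_node[1]
    result = solve_plane_stress(
        mesh.nodes,
        mesh.elements,
        materials.e_mpa,
        materials.nu,
        mesh.thickness_t,
        f,
        spring_nodes=load.spring_nodes,
        spring_k_per_node=load.spring_k_per_node,
        hinge=load.hinge,
    )
    result.extras.update(
        {
            "n_load_nodes": int(load.load_nodes.size),
            "n_spring_nodes": int(load.spring_nodes.size),
            "n_hinge_nodes": int(load.hinge.slave_nodes.size),
            "force_dir": load.force_dir.tolist(),
        }
    )
    return result
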