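"""Mesh energetics and stretch-triggered division, step by step.

Builds a small cell chain, evaluates the four-term tissue energy and its
analytic forces, stretches one cell past the division threshold, and splits
it at the apical/basal edge midpoints — printing the quantities the
simulation engine uses internally.
"""

import numpy as np

import midlinesim as ms
from midlinesim.dynamics import CellStates
from midlinesim.energy import edge_elastic_energy, tissue_energy, tissue_forces

mesh = ms.make_initial_mesh(6, tissue="FP")
params = ms.MechanicalParams()
print(f"fresh 6-cell chain: U = {tissue_energy(mesh, params):.4f} "
      f"(areas {np.round([ms.cell_area(mesh, i) for i in range(3)], 3)}...)")

forces = tissue_forces(mesh, params)
print(f"max |force| on any vertex: {np.abs(forces).max():.4f}")

# stretch the posterior-most cell's posterior edge by 0.8 cell widths
mesh.vertices[mesh.cells[5, 1], 0] += 0.8
mesh.vertices[mesh.cells[5, 2], 0] += 0.8
u5 = edge_elastic_energy(mesh, 5, params.b)
print(f"after stretching cell 5: edge elastic energy U_5 = {u5:.3f} "
      f"(division threshold {ms.DivisionParams().U_th})")

states = CellStates(mesh.n_cells)
parent_area = ms.cell_area(mesh, 5)
new_id = ms.divide_cell(mesh, 5, states)
a1, a2 = ms.cell_area(mesh, 5), ms.cell_area(mesh, new_id)
print(f"divided cell 5: daughter areas {a1:.3f} + {a2:.3f} = {a1 + a2:.3f} "
      f"(parent {parent_area:.3f}); daughter migration forces = "
      f"{states.v[5]}, {states.v[new_id]}")
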