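"""Shared fixture builders used by several test modules."""

import numpy as np

import phytomesh as pm

# hole layout reused across repair tests: (length_fraction, width_fraction, r_mm)
HOLES_5 = [
    (0.15, 0.50, 2.0),
    (0.30, 0.30, 2.0),
    (0.50, 0.60, 2.0),
    (0.70, 0.40, 2.0),
    (0.85, 0.50, 2.0),
]

FINE_STRIP = pm.RibbonSpec(
    length=180.0, width=30.0, twist_turns=0.0, n_length=361, n_width=61
)


def punched_strip(n_holes: int = 5, spec: pm.RibbonSpec | None = None):
    """Flat strip with ``n_holes`` punched discs (from the shared layout)."""
    return pm.perforated_ribbon(spec or FINE_STRIP, HOLES_5[:n_holes])


def sphere_minus_face(sphere, face_index: int = 100):
    return pm.TriangleMesh(sphere.vertices, np.delete(sphere.faces, face_index, axis=0))
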