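"""Predict liquid-liquid coexistence curves of lysozyme in four buffers.

Builds the packaged coarse-grained HEWL model (hard sphere, sigma = 3.43 nm,
with M = 10 square-well surface sites of range 0.18 nm), takes each buffer's
zero-salt well depth eps0, and solves the TPT1 coexistence conditions.
"""

from patchyllps import binodal_curve, buffer_fixtures, cloud_point_temperature, hewl_model

model = hewl_model()

print("buffer        eps0/K    T_c/K   gamma_c   T_cloud(90)  T_cloud(125)")
print("                                (mg/mL)        /K           /K")
for buf in sorted(buffer_fixtures(), key=lambda b: -b.eps0):
    curve = binodal_curve(model, buf.eps0, n_temperatures=15)
    gamma_c = model.mass_concentration(curve.critical_density)
    t90 = cloud_point_temperature(90.0, model, buf, 0.0)
    t125 = cloud_point_temperature(125.0, model, buf, 0.0)
    print(
        f"{buf.name:<12} {buf.eps0:7.0f} {curve.critical_temperature:8.2f} "
        f"{gamma_c:8.1f} {t90:11.2f} {t125:12.2f}"
    )

print(
    "\nA deeper well (larger eps0) lifts the whole coexistence dome: phosphate"
    "\ndestabilizes lysozyme most (highest cloud point on cooling), cacodylate"
    "\nleast. The higher concentration, 125 mg/mL, sits closer to the dome apex"
    "\n(~231 mg/mL) and therefore clouds a degree or two earlier than 90 mg/mL."
)
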