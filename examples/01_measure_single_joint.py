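"""Measure one annotated joint: fossa frame, coordinates, disc-condyle angle.

A radiologist marks five points on the mid-condylar sagittal MRI slice
(millimetres): articular tubercle T, porus acusticus P, glenoid fossa
apex G, condyle center C and the posterior band of the disc D.  From
these the package builds the fossa coordinate frame (x posterior, y
superior, origin G) and the Drace disc-condyle angle (positive =
anterior)."""

from tmjmetrics import (
    LandmarkSet,
    build_fossa_frame,
    disc_condyle_angle,
    to_frame_coords,
)

landmarks = LandmarkSet(
    T=(-9.0, -5.0),     # anterior, below the fossa
    P=(10.0, -5.0),     # posterior
    G=(0.0, 0.0),       # fossa apex = origin
    C=(1.2, -6.4),      # condyle center
    D=(-2.0, -2.8),     # posterior band of the disc
    side="right",
)

frame = build_fossa_frame(landmarks)
condyle = to_frame_coords(landmarks.C, frame)
disc = to_frame_coords(landmarks.D, frame)
angle = disc_condyle_angle(landmarks)

print(f"condyle (x, y) = ({condyle.x:.2f}, {condyle.y:.2f}) mm")
print(f"disc    (x, y) = ({disc.x:.2f}, {disc.y:.2f}) mm")
print(f"disc-condyle angle = {angle:.1f} deg")
print()
print("x > 0 means behind the fossa apex, y < 0 below it; an angle well")
print("above +15 deg means the disc sits anterior of the condyle vertical,")
print("i.e. an anteriorly displaced disc.")
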