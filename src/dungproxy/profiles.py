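"""Default camera profiles for the two survey airframes.

Manufacturers print 35 mm-equivalent lens values, so true focal lengths
cannot be read off the spec sheet directly; these profiles pair the common
1/2.3-inch sensor (6.17 mm x 4.63 mm) with true focal lengths that
reproduce the validated ground coverage of each airframe (about
35 m x 26 m at 20 m for the Phantom-3 class; about 2.9 m x 2.1 m at 2 m
and a ~0.09 cm ground sampling distance for the Mavic class, whose
printed coverage pairs the long ground side with the 3000 px axis).
Profiles are defaults: a run config may override any constant.
"""

from .geometry import CameraModel

CAMERA_PROFILES: dict[str, CameraModel] = {
    # Rectangle-route airframe: 20 m flights, ~34.2 m x 25.7 m footprints.
    "phantom3": CameraModel(
        sensor_width_mm=6.17, sensor_length_mm=4.63,
        focal_length_mm=3.61, image_width_px=4000, image_height_px=3000),
    # Belt-route airframe: 2 m flights, ~2.87 m x 2.15 m footprints.
    "mavic": CameraModel(
        sensor_width_mm=6.17, sensor_length_mm=4.63,
        focal_length_mm=4.30, image_width_px=3000, image_height_px=4000),
}
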