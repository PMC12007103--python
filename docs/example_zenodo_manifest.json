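{
  "_comment": "Example manifest for an experimentally recorded lensless stack of an optically thin phase resolution target: three 8-bit in-line holograms at 4.5/6.5/8.5 mm camera-sample distance, 561 nm illumination, 2.4 um pixel pitch. Point the paths at the downloaded TIFF/PNG frames and run: gaborholo reconstruct --manifest <this file> --method iga --iterations 100 --sigma 2 --output out/",
  "pixel_pitch_m": 2.4e-06,
  "multiplex_mode": "distance",
  "camera": {"bit_depth": 8},
  "acquisition": {"exposure_s": 0.01},
  "frames": [
    {"path": "thin_target_z4p5mm.tif", "distance_m": 0.0045, "wavelength_m": 5.61e-07},
    {"path": "thin_target_z6p5mm.tif", "distance_m": 0.0065, "wavelength_m": 5.61e-07},
    {"path": "thin_target_z8p5mm.tif", "distance_m": 0.0085, "wavelength_m": 5.61e-07}
  ]
}
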