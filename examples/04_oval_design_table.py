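"""Design quantities of the single-file oval experiment.

For each occupant count on the 14.97 m oval: per-person gross space, net
space after subtracting the 28.8 cm average body depth (round-subtract-
round convention), and the Hall proxemic zone that net distance falls in.
Also shows the metronome floor-marker spacing that paces an imposed speed.
"""

from crowdeda.design import design_table, marker_spacing

print(design_table().to_string(index=False))
print()
for speed in (1.41, 0.86, 0.31, 0.19):
    print(f"speed {speed:.2f} m/s at 60 bpm -> marker spacing "
          f"{marker_spacing(speed, 60):.2f} m")
print("-> densities from 4 to 40 occupants sweep the interpersonal "
      "distance from the far social zone into the near intimate zone.")
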