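"""Unit-cell volumes of two competing lattice settings of one hydrate.

During indexing, a crystal can admit more than one plausible cell.  Here
the same bisdemethoxycurcumin dihydrate lattice was describable either as
a small monoclinic cell (beta far from 90 degrees) or as a cell with a
near-90-degree beta and a tripled long axis; the volume ratio close to 5
reflects the five independent molecules of the larger setting.
"""

from solvscreen import cell_volume

small = cell_volume(20.254, 7.2380, 11.5070, 90, 110.522, 90)
large = cell_volume(20.255, 7.2390, 53.895, 90, 90.034, 90)
print(f"small monoclinic setting: {small:8.1f} A^3")
print(f"large alternative setting: {large:7.0f} A^3")
print(f"volume ratio: {large / small:.3f}")
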