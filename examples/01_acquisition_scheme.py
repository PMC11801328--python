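"""Build the multi-echo multi-b acquisition scheme and inspect its shells.

The protocol interleaves 60 diffusion preparations (13 b-shells between
5 and 1600 s/mm^2 with 3-15 directions each) with four gradient-echo
readouts at TE = 78/114/150/186 ms, giving 240 volumes per subject.
"""

import numpy as np

from placenta_dwr import build_protocol_scheme, read_scheme, write_scheme

scheme = build_protocol_scheme()
print(f"measurements: {len(scheme)}   shortest TE: {scheme.te_min:g} ms")

b = scheme.b_values
te = scheme.echo_times
print("\nshell table (directions per echo time):")
for shell in np.unique(b):
    n = int(np.sum((b == shell) & (te == scheme.te_min)))
    print(f"  b = {shell:6g} s/mm^2 : {n:2d} directions x {len(np.unique(te))} TEs")

write_scheme(scheme, "/tmp/scheme.bval", "/tmp/scheme.bvec", "/tmp/scheme.te")
back = read_scheme("/tmp/scheme.bval", "/tmp/scheme.bvec", "/tmp/scheme.te")
print(f"\nsidecar round trip: {len(back)} measurements re-read, "
      f"te_min {back.te_min:g} ms")
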