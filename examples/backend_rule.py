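"""The host/accelerator placement rule for submodule groups.

A group runs on the host only when its accelerator runtime (plus accelerator
auxiliary time) exceeds the full round trip of moving the data to the host,
computing there, and moving it back. Ties stay on the accelerator because the
data already lives there.
"""

from ivoct import TimingProfile, select_backend

profiles = {
    "clustering (irregular, branchy)": TimingProfile(
        t_device=5.0, t_device_aux=1.0, t_d2h=1.0, t_host=2.0, t_h2d=1.0, t_host_aux=0.0
    ),
    "FFT batch (regular, massive)": TimingProfile(
        t_device=2.0, t_device_aux=0.0, t_d2h=1.0, t_host=5.0, t_h2d=1.0, t_host_aux=0.0
    ),
    "borderline group (tie)": TimingProfile(
        t_device=3.0, t_device_aux=0.0, t_d2h=1.0, t_host=1.0, t_h2d=1.0, t_host_aux=0.0
    ),
}
for name, p in profiles.items():
    device = p.t_device + p.t_device_aux
    host = p.t_d2h + p.t_host + p.t_h2d + p.t_host_aux
    print(f"{name}: device {device:.1f}s vs host round trip {host:.1f}s -> {select_backend(p)}")
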