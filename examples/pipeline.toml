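# Default study configuration: 5.08 x 5.08 cm NaI(Tl), 869 linear channels
# over 0-3100 keV, G(E) with Kmax=7/M=0 per geometry (0/45/90 deg +
# isotropic), GP over the pooled G data, 100 realizations, 1.96-SD bands.

[detector]
diameter_cm = 5.08
height_cm = 5.08
density_g_cm3 = 3.6

[grid]
n_channels = 869
grid_min_keV = 0.0
grid_max_keV = 3100.0

[broadening]
broaden_a = 1.0
broaden_b = 1.8
broaden_c = 0.0
fwhm_factor = 2.36

[conditions]
angles_deg = [0.0, 45.0, 90.0]
include_isotropic = true
n_iso_angles = 16

[calibration]
n_calibration = 30
calib_min_keV = 50.0
calib_max_keV = 3000.0
n_test = 20
ref_energy_keV = 662.0

[gfit]
kmax = 7
m_offset = 0
log_base = "10"

[gp]
gp_stride = 8
n_samples = 100
realization_noise = "correlated"
gp_n_starts = 8

[run]
seed = 1
output_dir = "gdose_run"
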