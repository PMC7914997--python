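# Default parameter profile for the endothelial ATP + shear Ca2+ model.
# Units: concentrations uM, time s, shear Pa; membrane quantities SI.
#
# Provenance: the model family (IP3/CICR store release, SERCA restore with a
# quadratic leak, saturating efflux, first-order protein buffering, P2X4 and
# strain-energy-gated TRP influx) fixes the functional forms; the constants
# below sit in the physiological ranges used across that family and were
# calibrated as one consistent profile so that the resting state is a true
# equilibrium at C0 = 0.1 uM and the 0.1 Hz / 10 uM-peak sinusoidal-ATP
# validation protocol yields the characteristic sharp onset peak (~25 s)
# entrained at the drive frequency. Every value can be overridden via
# default_params(**overrides) or a config file.

# --- IP3 turnover ---
k1 = 0.07       # max IP3 production rate (uM/s); sets the slow ignition latency
k2 = 0.04       # IP3 degradation rate (1/s); ~25 s lifetime
Kc = 1.0       # ATP concentration for half-maximal PLC activation (uM)
K1 = 0.6        # Ca2+ concentration for half-maximal PLC activation (uM)

# --- store release / restore / leak ---
k3 = 60.0       # max CICR release rate constant (1/s)
k4 = 20.0      # max SERCA restore rate (uM/s)
k5 = 2.0e-5    # store leak rate (1/(uM s)); with k4 sets Cs0 = 400 uM
K2 = 1.0        # IP3 sensitivity of store release (uM)
K3 = 0.15      # Ca2+ sensitivity of the restore pump (uM)
KCICR = 0.8     # Ca2+ sensitivity of CICR (uM)

# --- efflux (PMCA/NCX lumped) ---
k8 = 25.0      # maximum efflux rate (uM/s)
K4 = 0.4       # efflux Michaelis constant (uM)

# --- cytosolic protein buffering ---
k6 = 50.0      # on-rate (1/(uM s))
k7 = 60.0      # off-rate (1/s); Kd = k7/k6 = 1.2 uM
BT = 120.0     # total buffer site concentration (uM)

# --- compartments ---
Vc_over_Vs = 8.0   # cytosol-to-store volume ratio
Cex = 1500.0       # extracellular Ca2+ (uM)
C0 = 0.1           # resting cytosolic Ca2+ (uM)

# --- P2X4 (ATP-gated) influx ---
kp2x4 = 5.0e-4  # flux rate (1/s)
Kp2x4 = 3.0        # ATP sensitivity (uM); three-site binding

# --- TRPV4/TRPC1 (mechanosensitive) influx and gating ---
qmax = 2.0e-5   # max inflow rate (1/(uM s))
alpha = 10.0       # no-load gating constant; open probability 1/(1+alpha) at rest
fe = 0.01          # fraction of membrane strain energy gating the channels
T = 310.0          # temperature (K)
N = 8.5e8          # shear-gated channel density (1/m2), ~1 per um2
eps_m = 0.1        # fraction of the applied load borne by the membrane
l = 3.0e-5         # cell length in the flow direction (m)
delta_m = 1.0e-4   # membrane shear modulus (N/m)
gating_scale = 8.0 # gating-energy normalisation factor (the "8" of 8kTN)

# --- p2 (IP3 gate) and p3 (Ca2+ decay gate) ---
a1 = 4.0
b1 = 0.1
Ki = 0.3           # uM^3, acts on i^3
c1 = 0.1
c2 = 0.9
c3 = 5.0           # 1/uM
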