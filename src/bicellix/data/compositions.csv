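# Physically derived composition fixtures (not instrument-specific fits).
# n_electrons: electrons per molecule; sum_b: coherent neutron scattering
# length per molecule in Angstrom (1 fm = 1e-5 A); volume in A^3.
# dmpc_tail volume is the geometric fixture A_L * H_tail / 2 = 61.8 * 14.4.
name,n_electrons,sum_b,volume
water,10,-1.679e-5,29.9
heavy_water,10,1.9146e-4,30.0
dmpc_tail,210,-2.920e-4,889.92
dmpc_head,164,6.00e-4,320.0
chapso,344,6.365e-4,838.0
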