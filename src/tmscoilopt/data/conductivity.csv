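tissue,conductivity_S_per_m,density_g_per_cm3
Blood,7.00e-1,1.05
Bone,2.03e-2,1.91
Bone marrow,2.90e-2,0.98
Cartilage,1.75e-1,1.10
Cerebellum,1.24e-1,1.05
Dura mater,5.01e-1,1.17
Cerebrospinal fluid,2.00,1.01
Commissura anterior,6.42e-2,1.04
Commissura posterior,6.42e-2,1.04
Connective tissue,3.85e-1,1.53
Eyes,2.00,1.00
Fat,4.23e-2,0.91
Grey matter,1.04e-1,1.04
Hippocampus,1.04e-1,1.04
Hypophysis,5.26e-1,1.05
Hypothalamus,5.26e-1,1.05
Internal air,0,1.00
Lymph node,5.26e-1,1.04
Mucosa,8.25e-4,1.10
Muscle,3.31e-1,1.09
Midbrain,1.24e-1,1.04
Nerve,3.02e-1,1.07
Pineal gland,5.26e-1,1.05
Pituitary,5.26e-1,1.05
Pons,1.24e-1,1.05
Salivary gland,3.02e-2,1.08
Skin,2.00e-4,1.11
Teeth,2.03e-2,2.18
Thalamus,1.04e-1,1.04
Tongue,2.76e-1,1.09
White matter,6.42e-2,1.04
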