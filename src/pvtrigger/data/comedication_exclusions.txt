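# Concomitant-therapy exclusion list for the sensitivity analysis:
# NSAIDs, csDMARDs, glucocorticoids, biologics/targeted agents, other
# immunosuppressants commonly co-reported in juvenile idiopathic arthritis.
NAPROXEN
DICLOFENAC
CELECOXIB
IBUPROFEN
ACETAMINOPHEN
METHOTREXATE
LEFLUNOMIDE
SULFASALAZINE
HYDROXYCHLOROQUINE
PENICILLAMINE
HYDROCORTISONE
PREDNISONE
DEXAMETHASONE
METHYLPREDNISOLONE
TRIAMCINOLONE
PREDNISOLONE
BUDESONIDE
BETAMETHASONE
CORTISONE
ADALIMUMAB
ETANERCEPT
TOCILIZUMAB
INFLIXIMAB
CANAKINUMAB
ANAKINRA
RUXOLITINIB
GOLIMUMAB
SECUKINUMAB
TOFACITINIB
ABATACEPT
SARILUMAB
RITUXIMAB
USTEKINUMAB
CERTOLIZUMAB
TACROLIMUS
CYCLOSPORINE
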