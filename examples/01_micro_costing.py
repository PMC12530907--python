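"""Bottom-up micro-costing: itemize resources, correct prices, aggregate.

Builds a small itemized ledger for a surgical admission, corrects each unit
price to a common reference period with a price-index series, and sums
quantity x corrected price per cost category.
"""

from slnbcost import LedgerItem, PriceIndexSeries, aggregate_ledger, inflate_price, parse_brl

index = PriceIndexSeries({"2022-06": 100.0, "2023-06": 105.9, "2024-06": 110.3})

ledger = [
    LedgerItem("preoperative_staging", "neck MRI", parse_brl("1.030,50"), 1, "2022-06"),
    LedgerItem("medical", "surgeon hours", 420.0, 3, "2023-06"),
    LedgerItem("paramedical", "nursing shift", 180.0, 2, "2023-06"),
    LedgerItem("structural", "theatre hour", 610.0, 2, "2024-06"),
    LedgerItem("rehabilitation", "physiotherapy session", 95.0, 4, "2024-06"),
]

totals = aggregate_ledger(ledger, index, reference_period="2024-06")
print("Per-category totals at 2024-06 prices (R$):")
for category, total in totals.by_category.items():
    print(f"  {category:<22s} {total:10.2f}")
print(f"  {'grand total':<22s} {totals.grand_total:10.2f}")

mri_2024 = inflate_price(1030.50, index, "2022-06", "2024-06")
print(f"\nThe 2022 MRI price of R$1,030.50 is R${mri_2024:.2f} in 2024 terms:")
print("each item enters the totals at reference-period prices, so ledgers")
print("quoted across different years are directly comparable.")
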