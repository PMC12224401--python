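term,category,match_kind,priority
verdulería,fruit_vegetable_store,name,2
frutería,fruit_vegetable_store,name,2
frutas y verduras,fruit_vegetable_store,name,2
carnicería,fresh_food_retail,name,2
pescadería,fresh_food_retail,name,2
panadería,fresh_food_retail,name,2
pastelería,fresh_food_retail,name,2
mercado,fresh_food_retail,name,3
almacén,small_food_retail,name,2
abarrotes,small_food_retail,name,2
tienda de abarrotes,small_food_retail,name,2
bodega,small_food_retail,name,2
minimercado,small_food_retail,name,2
provisiones,small_food_retail,name,3
despensa,small_food_retail,name,3
supermercado,supermarket,name,2
hipermercado,supermarket,name,2
supermarket,supermarket,both,2
restaurante,ready_for_consumption,name,2
restaurant,ready_for_consumption,both,2
restorán,ready_for_consumption,name,2
cafetería,ready_for_consumption,name,2
café,ready_for_consumption,name,3
fuente de soda,ready_for_consumption,name,2
pizzería,ready_for_consumption,name,2
sanguchería,ready_for_consumption,name,2
sushi,ready_for_consumption,name,3
cocinería,ready_for_consumption,name,2
pollería,ready_for_consumption,name,2
comida casera,ready_for_consumption,name,2
minimarket,convenience_store,name,2
ok market,convenience_store,name,1
pronto copec,convenience_store,name,1
spid,convenience_store,name,1
big john,convenience_store,name,1
upa,convenience_store,name,1
mcdonald's,fast_food_chain,name,1
burger king,fast_food_chain,name,1
kfc,fast_food_chain,name,1
subway,fast_food_chain,name,1
domino's pizza,fast_food_chain,name,1
telepizza,fast_food_chain,name,1
doggis,fast_food_chain,name,1
juan maestro,fast_food_chain,name,1
pedro juan y diego,fast_food_chain,name,1
papa john's,fast_food_chain,name,1
heladería,candy_ice_cream,name,2
dulcería,candy_ice_cream,name,2
confitería,candy_ice_cream,name,2
chocolatería,candy_ice_cream,name,2
helados,candy_ice_cream,name,3
dulces,candy_ice_cream,name,3
greengrocer,fruit_vegetable_store,provider_type,2
butcher_shop,fresh_food_retail,provider_type,2
fish_market,fresh_food_retail,provider_type,2
bakery,fresh_food_retail,provider_type,2
grocery_store,small_food_retail,provider_type,2
cafe,ready_for_consumption,provider_type,2
meal_takeaway,ready_for_consumption,provider_type,2
convenience_store,convenience_store,provider_type,2
fast_food_restaurant,fast_food_chain,provider_type,2
ice_cream_shop,candy_ice_cream,provider_type,2
candy_store,candy_ice_cream,provider_type,2
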